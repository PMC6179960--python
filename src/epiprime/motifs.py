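"""PWM scanning, exact threshold calibration, GC-matched motif enrichment.

Motifs are position probability matrices scored by log2 odds against a
background base composition (probabilities floored at 1e-3 before the log so
scores stay finite). Per-motif score thresholds are calibrated to an exact
null p-value by dynamic programming over the discretised score distribution
under the background model — the same construction FIMO-style scanners use.

Enrichment of a motif at a target region set is a one-sided hypergeometric
test of region-level hit counts against a GC-matched background set, with
BH correction across the motif library.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "PWM",
    "MotifHit",
    "calibrate_threshold",
    "scan",
    "scan_regions",
    "region_gc",
    "gc_matched_background",
    "motif_enrichment",
    "motif_set_comparison",
    "nominate_tfs",
    "read_pwms",
    "write_pwms",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate("ACGT")}
PROB_FLOOR = 1e-3
# Log-odds scores are quantized to this grid so the threshold-calibration
# dynamic programme and the scanner share exactly the same discrete score
# space: the DP null tail is then exact for the scores the scanner computes,
# with no accumulation of per-position rounding error across the motif.
SCORE_QUANTUM = 0.005
_NEG = -1e9  # sentinel for N bases: windows containing N can never score a hit


@dataclass(frozen=True)
class PWM:
    """Position probability matrix for one motif.

    ``matrix`` is width x 4 (A, C, G, T) with rows summing to 1;
    ``background`` is the 4-vector the log-odds are taken against.
    """

    motif_id: str
    matrix: np.ndarray
    tf_name: str = ""
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(
            self, "background", np.asarray(self.background, dtype=float)
        )
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("matrix must be width x 4")
        if m.shape[0] < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("matrix rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """width x 4 log2-odds, floored probabilities, quantized scores.

        Scores are rounded to the :data:`SCORE_QUANTUM` grid so threshold
        calibration is exact for the scores scanning actually uses.
        """
        p = np.maximum(self.matrix, PROB_FLOOR)
        b = np.maximum(self.background, PROB_FLOOR)
        raw = np.log2(p) - np.log2(b)[None, :]
        return np.round(raw / SCORE_QUANTUM) * SCORE_QUANTUM

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    chrom: str
    position: int  # 0-based offset of the window start
    strand: str
    score: float


def calibrate_threshold(
    pwm: PWM, pvalue: float = 1e-4, bin_width: float = SCORE_QUANTUM
) -> float:
    """Smallest score whose null tail probability is <= ``pvalue``.

    The null is the background model i.i.d. over the motif width; the score
    distribution is computed exactly by position-wise dynamic programming on a
    discretised score grid (bin width <= 0.01).
    """
    if not (0 < pvalue < 1):
        raise ValueError("pvalue must be in (0, 1)")
    L = pwm.log_odds()
    q = np.round(L / bin_width).astype(int)  # integer scores per (pos, base)
    # convolve the per-position score distributions one motif column at a time
    bg = np.maximum(pwm.background, PROB_FLOOR)
    bg = bg / bg.sum()
    cur = np.zeros(1)
    cur[0] = 1.0
    cur_lo = 0
    for j in range(pwm.width):
        qs = q[j]
        new_lo = cur_lo + qs.min()
        new_hi = cur_lo + len(cur) - 1 + qs.max()
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            shift = cur_lo + qs[b] - new_lo
            new[shift : shift + len(cur)] += bg[b] * cur
        cur, cur_lo = new, new_lo
    tail = np.cumsum(cur[::-1])[::-1]  # tail[i] = P(S_int >= cur_lo + i)
    ok = np.flatnonzero(tail <= pvalue)
    if ok.size == 0:
        logger.warning(
            "%s: pvalue %g below minimal attainable tail; threshold set just "
            "above the maximal score (no sequence can reach it)",
            pwm.motif_id,
            pvalue,
        )
        return float((cur_lo + len(cur)) * bin_width)
    return float((cur_lo + ok[0]) * bin_width)


def null_tail_probability(
    pwm: PWM, threshold: float, bin_width: float = SCORE_QUANTUM
) -> float:
    """Exact null probability that a background window scores >= threshold.

    Same dynamic programme as :func:`calibrate_threshold`; useful for
    verifying a calibrated threshold against simulation.
    """
    L = pwm.log_odds()
    q = np.round(L / bin_width).astype(int)
    bg = np.maximum(pwm.background, PROB_FLOOR)
    bg = bg / bg.sum()
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(pwm.width):
        qs = q[j]
        new_lo = cur_lo + qs.min()
        new = np.zeros(cur_lo + len(cur) - 1 + qs.max() - new_lo + 1)
        for b in range(4):
            shift = cur_lo + qs[b] - new_lo
            new[shift : shift + len(cur)] += bg[b] * cur
        cur, cur_lo = new, new_lo
    k = int(np.ceil(threshold / bin_width)) - cur_lo
    if k <= 0:
        return 1.0
    if k >= len(cur):
        return 0.0
    return float(cur[k:].sum())


def encode(sequence: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _CODE.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, lodds: np.ndarray) -> np.ndarray:
    """Score of every window start under a width x 4 log-odds matrix."""
    w = lodds.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    # 5th row = N sentinel
    L = np.vstack([lodds.T, np.full((1, w), _NEG)])  # 5 x w
    scores = np.zeros(n)
    for j in range(w):
        scores += L[codes[j : j + n], j]
    return scores


def scan(
    pwm: PWM, sequence: str, threshold: float, chrom: str = ""
) -> list[MotifHit]:
    """Scan both strands; report positions where max(fwd, rev) >= threshold.

    The reverse-strand score at a window is the forward score of the motif's
    reverse complement, so region-level hits are strand-symmetric.
    """
    codes = encode(sequence)
    L = pwm.log_odds()
    fwd = _window_scores(codes, L)
    rc = L[::-1, ::-1]  # reverse complement of the motif
    rev = _window_scores(codes, rc)
    hits = []
    # tiny tolerance: scores are sums of grid-quantized floats, so exact
    # lumps at the threshold must not be lost to representation error
    threshold = threshold - 1e-9
    for i in np.flatnonzero(np.maximum(fwd, rev) >= threshold):
        if fwd[i] >= rev[i]:
            strand, score = "+", fwd[i]
        else:
            strand, score = "-", rev[i]
        hits.append(
            MotifHit(
                motif_id=pwm.motif_id,
                chrom=chrom,
                position=int(i),
                strand=strand,
                score=float(score),
            )
        )
    return hits


def scan_regions(
    pwm: PWM,
    regions: PeakSet,
    genome: dict[str, str],
    threshold: float,
) -> pd.Series:
    """Boolean per region: does the region contain >= 1 hit of the motif."""
    out = {}
    for rid, iv in zip(regions.region_ids(), regions):
        seq = genome[iv.chrom][iv.start : iv.end]
        out[rid] = len(scan(pwm, seq, threshold, chrom=iv.chrom)) > 0
    return pd.Series(out, dtype=bool)


def region_gc(regions: PeakSet, genome: dict[str, str]) -> np.ndarray:
    """GC fraction of each region's extracted sequence."""
    gc = np.empty(len(regions))
    for i, iv in enumerate(regions):
        seq = genome[iv.chrom][iv.start : iv.end].upper()
        n = len(seq)
        gc[i] = (seq.count("G") + seq.count("C")) / n if n else 0.0
    return gc


def gc_matched_background(
    targets: PeakSet,
    pool: PeakSet,
    genome: dict[str, str],
    ratio: int = 2,
    bins: int = 10,
    seed: int = 0,
) -> PeakSet:
    """Sample a background set GC-matched to the targets.

    Bin edges are the target GC quantiles (``bins`` bins); within each bin,
    ``ratio`` x the target count is sampled from the pool without replacement
    (capped at availability with a warning). Deterministic given ``seed``.
    """
    if len(targets) == 0:
        raise ValueError("empty target set")
    target_keys = {(iv.chrom, iv.start, iv.end) for iv in targets}
    pool_iv = [iv for iv in pool if (iv.chrom, iv.start, iv.end) not in target_keys]
    pool = PeakSet(pool_iv, label=pool.label)
    tgc = region_gc(targets, genome)
    pgc = region_gc(pool, genome)
    edges = np.quantile(tgc, np.linspace(0, 1, bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    tbin = np.digitize(tgc, edges[1:-1])
    pbin = np.digitize(pgc, edges[1:-1])
    rng = np.random.default_rng(seed)
    chosen: list[GenomicInterval] = []
    for b in range(bins):
        want = ratio * int((tbin == b).sum())
        if want == 0:
            continue
        avail = np.flatnonzero(pbin == b)
        if avail.size < want:
            logger.warning(
                "GC bin %d: only %d of %d background regions available",
                b,
                avail.size,
                want,
            )
            want = avail.size
        take = rng.choice(avail, size=want, replace=False)
        chosen.extend(pool[int(i)] for i in take)
    return PeakSet(chosen, label=f"{targets.label}/gc_background")


def motif_enrichment(
    targets: PeakSet,
    background: PeakSet,
    genome: dict[str, str],
    pwm_library: list[PWM],
    thresholds: dict[str, float] | None = None,
    threshold_pvalue: float = 1e-4,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Region-level motif enrichment of targets vs background.

    One-sided hypergeometric p per motif: drawing ``n_target`` regions from
    the combined urn, how extreme is the observed number of hit-bearing target
    regions. Returns a motif-indexed table with hit counts, odds ratio
    (Haldane-corrected), p, BH-FDR and the enriched flag
    (fdr < ``fdr_cut`` and odds ratio > 1).
    """
    if len(targets) == 0:
        raise ValueError("empty target set")
    thresholds = thresholds or {}
    rows = {}
    for pwm in pwm_library:
        thr = thresholds.get(pwm.motif_id)
        if thr is None:
            thr = calibrate_threshold(pwm, threshold_pvalue)
        k_t = int(scan_regions(pwm, targets, genome, thr).sum())
        k_b = int(scan_regions(pwm, background, genome, thr).sum())
        n_t, n_b = len(targets), len(background)
        N, K = n_t + n_b, k_t + k_b
        p = float(stats.hypergeom.sf(k_t - 1, N, K, n_t))
        orr = ((k_t + 0.5) / (n_t - k_t + 0.5)) / ((k_b + 0.5) / (n_b - k_b + 0.5))
        rows[pwm.motif_id] = {
            "tf_name": pwm.tf_name,
            "n_target": n_t,
            "n_target_hit": k_t,
            "n_bg": n_b,
            "n_bg_hit": k_b,
            "odds_ratio": orr,
            "p": p,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "motif_id"
    table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["enriched"] = (table["fdr"] < fdr_cut) & (table["odds_ratio"] > 1.0)
    return table


def motif_set_comparison(
    enriched_a: set[str], enriched_b: set[str]
) -> dict[str, set[str]]:
    """Venn partition of two enriched-motif sets."""
    a, b = set(enriched_a), set(enriched_b)
    return {"unique_a": a - b, "unique_b": b - a, "common": a & b}


def nominate_tfs(
    astro_enrichment: pd.DataFrame,
    neuro_enrichment: pd.DataFrame,
    expr: pd.DataFrame,
    stage: str,
    motif_to_gene: dict[str, str],
    min_expr: float = 1.0,
) -> pd.DataFrame:
    """Rank TF candidates for one stage from the lineage motif comparison.

    Candidates are motifs enriched at the astro stage's unique peaks but not
    at the matched neuro stage's (motifs enriched in both are kept with
    category "common"); each motif maps to its TF gene, which must be
    expressed (>= ``min_expr`` on the log2-normalised scale) at the stage.
    Unmappable motifs are retained and flagged. Ranked by enrichment p.
    """
    ven = motif_set_comparison(
        set(astro_enrichment.index[astro_enrichment["enriched"]]),
        set(neuro_enrichment.index[neuro_enrichment["enriched"]]),
    )
    rows = []
    for category, motifs in (("unique", ven["unique_a"]), ("common", ven["common"])):
        for m in sorted(motifs):
            gene = motif_to_gene.get(m)
            expressed = None
            if gene is not None and gene in expr.index:
                expressed = bool(expr.loc[gene, stage] >= min_expr)
            rows.append(
                {
                    "motif_id": m,
                    "tf_gene": gene,
                    "category": category,
                    "p": float(astro_enrichment.loc[m, "p"]),
                    "expressed": expressed,
                    "mappable": gene is not None,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["motif_id", "tf_gene", "category", "p", "expressed", "mappable"],
    )
    if len(table):
        expressed = np.array([bool(v) for v in table["expressed"]])
        keep = (~table["mappable"]) | expressed
        table = table[keep].sort_values(["category", "p"], ascending=[False, True])
        # "unique" sorts after "common" alphabetically; put unique first
        table = pd.concat(
            [table[table["category"] == "unique"], table[table["category"] == "common"]]
        ).reset_index(drop=True)
    return table


def load_genome(path) -> dict[str, str]:
    """Load a FASTA genome into an in-memory {chrom: sequence} dict."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def read_pwms(path) -> list[PWM]:
    """Read a JASPAR-like PWM text file.

    Records start with '>motif_id tf_name'; the following four lines are
    'A|C|G|T  p1 p2 ... pw'.
    """
    pwms = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected '>' header at line {i + 1}")
        parts = lines[i][1:].split()
        motif_id = parts[0]
        tf_name = parts[1] if len(parts) > 1 else ""
        rows = {}
        for j in range(1, 5):
            base, *vals = lines[i + j].split()
            rows[base.upper()] = [float(v) for v in vals]
        matrix = np.array([rows[b] for b in BASES]).T
        pwms.append(PWM(motif_id=motif_id, matrix=matrix, tf_name=tf_name))
        i += 5
    return pwms


def write_pwms(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.tf_name}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(f"{v:.6f}" for v in pwm.matrix[:, bi])
                fh.write(f"{base} {vals}\n")
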
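"""Binned read-count tracks, region quantification, enrichment and peak calling.

A :class:`BinnedTrack` stands in for aligned read coverage: one vector of
non-negative counts per chromosome at a fixed bin size. Enrichment over a
genomic-input track is computed as a pseudocounted, library-size normalised
log2 ratio ("log two-fold change above the genomic input"), the quantity the
profile plots and heatmaps display.

The peak caller is a deliberately minimal input-free caller: a one-sided
Poisson test per bin against a dynamic lambda = max(global rate, local rate in
+-5 kb), BH-corrected, with a fold-change floor and single-gap merging.
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
    "BinnedTrack",
    "SignalMatrix",
    "ProfileMatrix",
    "quantify",
    "log2_enrichment",
    "enrichment_matrix",
    "profile_matrix",
    "call_peaks",
    "marked_status",
    "read_track",
    "write_track",
]

logger = logging.getLogger(__name__)


@dataclass
class BinnedTrack:
    """Per-chromosome binned counts for one condition.

    ``counts`` maps chromosome name to a 1-D array of non-negative values;
    bin i covers [i*bin_size, (i+1)*bin_size). ``library_size`` is the total
    count over all chromosomes.
    """

    condition: str
    bin_size: int
    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.counts = {c: np.asarray(v, dtype=float) for c, v in self.counts.items()}
        for c, v in self.counts.items():
            if (v < 0).any():
                raise ValueError(f"negative counts on {c}")

    @property
    def library_size(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    def chrom_length(self, chrom: str) -> int:
        return len(self.counts[chrom]) * self.bin_size


@dataclass
class SignalMatrix:
    """regions x conditions table of raw counts or log2 enrichment."""

    regions: PeakSet
    values: pd.DataFrame  # index = region ids, columns = condition labels
    kind: str  # "raw" | "log2_enrichment"

    def __post_init__(self) -> None:
        if self.kind not in ("raw", "log2_enrichment"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if len(self.values) != len(self.regions):
            raise ValueError("values rows must match regions")
        if self.kind == "log2_enrichment" and not np.isfinite(
            self.values.to_numpy()
        ).all():
            raise ValueError("log2 enrichment values must be finite")

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProfileMatrix:
    """regions x position-bins matrix around region midpoints for one condition."""

    condition: str
    window: int
    values: np.ndarray  # regions x n_bins
    region_ids: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def profile(self) -> np.ndarray:
        """Column means: the profile-plot curve."""
        return self.values.mean(axis=0)


def quantify(track: BinnedTrack, regions: PeakSet) -> np.ndarray:
    """Per-region count: bin counts weighted by fractional bin-region overlap.

    Additive over any partition of a region. Raises KeyError when a region's
    chromosome is missing from the track.
    """
    out = np.empty(len(regions), dtype=float)
    for i, iv in enumerate(regions):
        out[i] = _quantify_span(track, iv.chrom, iv.start, iv.end)
    return out


def _quantify_span(track: BinnedTrack, chrom: str, start: float, end: float) -> float:
    if chrom not in track.counts:
        raise KeyError(f"chromosome {chrom} missing from track {track.condition!r}")
    c = track.counts[chrom]
    bs = track.bin_size
    start = max(0.0, start)
    end = min(float(len(c) * bs), end)
    if end <= start:
        return 0.0
    first, last = int(start // bs), int(np.ceil(end / bs)) - 1
    total = 0.0
    for b in range(first, last + 1):
        lo, hi = b * bs, (b + 1) * bs
        frac = (min(end, hi) - max(start, lo)) / bs
        total += c[b] * frac
    return total


def log2_enrichment(
    chip: float | np.ndarray,
    input_: float | np.ndarray,
    chip_lib: float,
    input_lib: float,
    pseudocount: float = 1.0,
) -> float | np.ndarray:
    """log2( ((chip+p)/chip_lib) / ((input+p)/input_lib) ).

    Invariant to multiplying both library sizes by a constant; the pseudocount
    keeps the ratio finite for empty regions.
    """
    if chip_lib <= 0 or input_lib <= 0:
        raise ValueError("library sizes must be positive")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    chip = np.asarray(chip, dtype=float)
    input_ = np.asarray(input_, dtype=float)
    if (chip < 0).any() or (input_ < 0).any():
        raise ValueError("counts must be non-negative")
    val = np.log2((chip + pseudocount) / chip_lib) - np.log2(
        (input_ + pseudocount) / input_lib
    )
    return float(val) if val.ndim == 0 else val


def enrichment_matrix(
    tracks: dict[str, BinnedTrack],
    input_track: BinnedTrack,
    regions: PeakSet,
    pseudocount: float = 1.0,
) -> SignalMatrix:
    """log2-over-input SignalMatrix for several conditions over one region set."""
    inp = quantify(input_track, regions)
    cols = {}
    for label, tr in tracks.items():
        chip = quantify(tr, regions)
        cols[label] = log2_enrichment(
            chip, inp, tr.library_size, input_track.library_size, pseudocount
        )
    df = pd.DataFrame(cols, index=regions.region_ids())
    return SignalMatrix(regions=regions, values=df, kind="log2_enrichment")


def profile_matrix(
    track: BinnedTrack,
    regions: PeakSet,
    window: int = 2000,
    n_bins: int = 41,
    input_track: BinnedTrack | None = None,
    pseudocount: float = 1.0,
) -> ProfileMatrix:
    """Signal in ``n_bins`` equal sub-windows spanning +-window around midpoints.

    ``n_bins`` must be odd so a center bin exists. With an input track, each
    cell is the log2 enrichment of that sub-window; otherwise raw counts.
    Regions whose window extends past a chromosome edge are dropped with a
    warning.
    """
    if n_bins % 2 == 0:
        raise ValueError("n_bins must be odd")
    if window < track.bin_size:
        raise ValueError("window must be at least one bin")
    sub = 2.0 * window / n_bins
    rows, ids = [], []
    dropped = 0
    for iv, rid in zip(regions, regions.region_ids()):
        mid = iv.midpoint
        lo = mid - window
        if lo < 0 or mid + window > track.chrom_length(iv.chrom):
            dropped += 1
            continue
        chip_row = np.array(
            [
                _quantify_span(track, iv.chrom, lo + j * sub, lo + (j + 1) * sub)
                for j in range(n_bins)
            ]
        )
        if input_track is not None:
            inp_row = np.array(
                [
                    _quantify_span(
                        input_track, iv.chrom, lo + j * sub, lo + (j + 1) * sub
                    )
                    for j in range(n_bins)
                ]
            )
            chip_row = log2_enrichment(
                chip_row,
                inp_row,
                track.library_size,
                input_track.library_size,
                pseudocount,
            )
        rows.append(chip_row)
        ids.append(rid)
    if dropped:
        logger.warning("profile_matrix: dropped %d edge regions", dropped)
    values = np.vstack(rows) if rows else np.empty((0, n_bins))
    return ProfileMatrix(
        condition=track.condition, window=window, values=values, region_ids=ids
    )


def call_peaks(
    track: BinnedTrack,
    fdr: float = 0.05,
    min_log2fc: float = 1.0,
    local_window: int = 5000,
) -> PeakSet:
    """Minimal input-free peak caller.

    Per bin, a one-sided Poisson p-value of the observed count against
    lambda = max(global mean rate, local mean rate in +-local_window), BH-FDR
    across all bins of the genome; significant bins additionally need
    log2(count/lambda) >= min_log2fc. Significant bins separated by a gap of
    at most one bin are merged into peaks.
    """
    chroms = sorted(track.counts)
    all_counts = np.concatenate([track.counts[c] for c in chroms]) if chroms else np.array([])
    if all_counts.size == 0 or all_counts.sum() == 0:
        return PeakSet([], label=f"{track.condition}/peaks")
    global_rate = all_counts.mean()
    half = max(1, int(round(local_window / track.bin_size)))
    kernel = np.ones(2 * half + 1)

    pvals, fold_ok, offsets = [], [], {}
    offset = 0
    for c in chroms:
        v = track.counts[c]
        # local mean with edge-aware normalisation
        s = np.convolve(v, kernel, mode="same")
        n = np.convolve(np.ones_like(v), kernel, mode="same")
        lam = np.maximum(global_rate, s / n)
        pvals.append(stats.poisson.sf(np.round(v) - 1, lam))
        with np.errstate(divide="ignore"):
            fold_ok.append(np.log2(np.where(v > 0, v, np.nan) / lam) >= min_log2fc)
        offsets[c] = offset
        offset += len(v)
    p = np.concatenate(pvals)
    sig = multipletests(p, alpha=fdr, method="fdr_bh")[0]
    sig &= np.nan_to_num(np.concatenate(fold_ok), nan=False)

    intervals = []
    for c in chroms:
        v = track.counts[c]
        mask = sig[offsets[c] : offsets[c] + len(v)]
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        start = prev = idx[0]
        runs = []
        for b in idx[1:]:
            if b - prev <= 2:  # gap of at most one non-significant bin
                prev = b
            else:
                runs.append((start, prev))
                start = prev = b
        runs.append((start, prev))
        bs = track.bin_size
        for k, (a, b) in enumerate(runs):
            intervals.append(
                GenomicInterval(c, int(a * bs), int((b + 1) * bs), name=f"{c}_peak{k}")
            )
    return PeakSet(intervals, label=f"{track.condition}/peaks")


def marked_status(sig: SignalMatrix, threshold: float = 1.0) -> pd.DataFrame:
    """Boolean regions x conditions table: enrichment >= threshold.

    Monotone in the threshold: raising it can only clear marks.
    """
    if sig.kind != "log2_enrichment":
        raise ValueError("marked_status requires a log2_enrichment SignalMatrix")
    return sig.values >= threshold


def read_track(path, condition: str = "", bin_size: int | None = None) -> BinnedTrack:
    """Read a bedGraph-like track (chrom, start, end, count), fixed bin size."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "count"],
    )
    if bin_size is None:
        bin_size = int((df["end"] - df["start"]).mode().iloc[0])
    counts: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        n = int(sub["end"].max() // bin_size)
        v = np.zeros(n, dtype=float)
        v[(sub["start"] // bin_size).to_numpy()] = sub["count"].to_numpy()
        counts[str(chrom)] = v
    return BinnedTrack(condition=condition, bin_size=bin_size, counts=counts)


def write_track(track: BinnedTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# condition={track.condition} bin_size={track.bin_size}\n")
        for chrom in sorted(track.counts):
            v = track.counts[chrom]
            bs = track.bin_size
            for i, x in enumerate(v):
                fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{x:g}\n")
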
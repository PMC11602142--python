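"""Range of sequence influence around breakpoints.

The span over which the genomic sequence influences breakage is
quantified in three steps:

1. a positional k-mer profile: canonical k-mer frequencies at every
   offset within a window (default 1 kb) centred on aligned breakpoints;
2. an RMSD curve: root-mean-squared deviation between the frequency
   vectors of adjacent offsets, computed per chromosome and averaged —
   sequence-driven breakage produces a characteristic central peak with
   an asymptotic decay, uniform breakpoints produce a flat noise floor;
3. deconvolution of the curve into up to three zero-mean Gaussian
   components plus a constant baseline. Each component's 95% confidence
   interval (3.92 sigma) defines a span of influence (short / medium /
   long range) and its peak amplitude as a fraction of the summed peak
   amplitudes defines its contribution. Peak fraction, not area under
   the curve, is used deliberately: a sharp short-range component would
   otherwise be dwarfed by a shallow long-range one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import least_squares

from ._sequence import canonical_code_tables, encode, kmer_codes, n_canonical_kmers
from .genomic_io import BreakpointSet, GenomeSequence

DEFAULT_HALF_WINDOW = 500  # 1 kb total window around the bond

# starting-value lattice for the Gaussian grid search
SIGMA_STARTS = (2.0, 5.0, 10.0, 25.0, 50.0, 100.0, 250.0)
AMPLITUDE_FACTORS = (0.25, 0.5, 1.0)
MIN_CONTRIBUTION = 0.05
SPAN_FACTOR = 2 * 1.96  # 95% CI width of a zero-mean Gaussian, in sigmas


@dataclass
class PositionalKmerProfile:
    """Canonical k-mer counts per offset relative to the breakpoint bond.

    ``counts[chrom]`` has shape (n_offsets, n_canonical_kmers); offset d
    tallies the k-mer starting at genome position bond+d together with
    its reverse complement. k-mers containing N are skipped.
    """

    k: int
    offsets: np.ndarray
    counts: Dict[str, np.ndarray]
    n_skipped_breakpoints: int = 0

    def frequencies(self, chrom: str) -> np.ndarray:
        c = self.counts[chrom].astype(np.float64)
        totals = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(totals > 0, c / totals, 0.0)
        return f


def positional_kmer_profile(
    genome: GenomeSequence,
    breaks: BreakpointSet,
    k: int = 8,
    half_window: int = DEFAULT_HALF_WINDOW,
) -> PositionalKmerProfile:
    """Tally canonical k-mers at offsets -half_window..+half_window
    around every usable breakpoint; per-chromosome counts retained.

    Breakpoints lacking half_window + k context on either side are
    skipped (counted in ``n_skipped_breakpoints``)."""
    canon_index, canon_codes = canonical_code_tables(k)
    n_canon = canon_codes.size
    offsets = np.arange(-half_window, half_window + 1, dtype=np.int64)
    counts: Dict[str, np.ndarray] = {}
    skipped = 0
    usable_total = 0
    for chrom in breaks.chroms:
        bonds = breaks.bonds[chrom]
        if bonds.size == 0:
            continue
        seq = genome.sequences[chrom]
        L = len(seq)
        ok = (bonds - half_window >= 0) & (bonds + half_window + k <= L)
        skipped += int((~ok).sum())
        bonds = bonds[ok]
        if bonds.size == 0:
            continue
        usable_total += bonds.size
        codes = kmer_codes(encode(seq), k)
        mat = np.zeros((offsets.size, n_canon), dtype=np.uint32)
        for i, d in enumerate(offsets):
            c = codes[bonds + d]
            c = c[c >= 0]  # skip N-containing k-mers
            if c.size:
                mat[i] = np.bincount(canon_index[c], minlength=n_canon)
        counts[chrom] = mat
    if usable_total == 0:
        raise ValueError("no usable breakpoints with sufficient context")
    return PositionalKmerProfile(k, offsets, counts, skipped)


@dataclass
class RmsdCurve:
    """RMSD between adjacent offsets' frequency vectors, chromosome-averaged.

    ``offsets`` are midpoints between the compared positions; length is
    one less than the profile's offset count."""

    offsets: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.offsets.shape != self.values.shape:
            raise ValueError("offsets and values must have equal length")

    def central_peak_stats(self, outer_fraction: float = 0.1) -> Dict[str, float]:
        """Central value vs the outer-decile noise floor: excess of the
        central RMSD over the median of the outer offsets, in units of
        their median absolute deviation."""
        n = self.values.size
        n_out = max(1, int(round(n * outer_fraction / 2)))
        outer = np.concatenate([self.values[:n_out], self.values[-n_out:]])
        med = float(np.median(outer))
        mad = float(np.median(np.abs(outer - med)))
        central = float(self.values[np.argmin(np.abs(self.offsets))])
        excess = (central - med) / mad if mad > 0 else np.inf if central > med else 0.0
        return {"central": central, "outer_median": med, "outer_mad": mad, "excess_mads": excess}


def adjacent_rmsd(profile: PositionalKmerProfile) -> RmsdCurve:
    """RMSD between adjacent offsets per chromosome, then unweighted mean
    over chromosomes. The mean inside the RMSD runs over the full
    canonical vocabulary, so it is invariant to vocabulary ordering."""
    if profile.offsets.size < 2:
        raise ValueError("need at least 2 offsets")
    per_chrom = []
    for chrom in sorted(profile.counts):
        f = profile.frequencies(chrom)
        d = np.diff(f, axis=0)
        per_chrom.append(np.sqrt(np.mean(d * d, axis=1)))
    values = np.mean(per_chrom, axis=0)
    mids = (profile.offsets[:-1] + profile.offsets[1:]) / 2.0
    return RmsdCurve(mids, values)


@dataclass
class RangeDeconvolution:
    """Zero-mean Gaussian mixture + constant baseline fitted to an RMSD curve."""

    amplitudes: np.ndarray
    sigmas: np.ndarray
    baseline: float
    sse: float
    converged: bool
    fallback_path: List[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return int(self.amplitudes.size)

    @property
    def contributions(self) -> np.ndarray:
        """Peak-amplitude fraction of each component (sums to 1)."""
        total = self.amplitudes.sum()
        if total == 0:
            return np.zeros_like(self.amplitudes)
        return self.amplitudes / total

    @property
    def spans(self) -> np.ndarray:
        """95%-CI width of each component, in bases (3.92 sigma)."""
        return SPAN_FACTOR * self.sigmas

    def predict(self, d: np.ndarray) -> np.ndarray:
        y = np.full_like(np.asarray(d, dtype=np.float64), self.baseline)
        for a, s in zip(self.amplitudes, self.sigmas):
            y = y + a * np.exp(-(np.asarray(d, float) ** 2) / (2 * s * s))
        return y

    def to_dict(self) -> dict:
        return {
            "components": [
                {"amplitude": float(a), "sigma": float(s), "span": float(sp), "contribution": float(c)}
                for a, s, sp, c in zip(self.amplitudes, self.sigmas, self.spans, self.contributions)
            ],
            "baseline": float(self.baseline),
            "sse": float(self.sse),
            "converged": bool(self.converged),
            "fallback_path": list(self.fallback_path),
        }


def _fit_m_components(
    d: np.ndarray, y: np.ndarray, m: int, baseline0: float, window: float
) -> Optional[Tuple[np.ndarray, np.ndarray, float, float]]:
    """Grid-searched bounded least squares for an m-component model.
    Returns (amplitudes, sigmas, baseline, sse) of the best converged
    start, or None if nothing converged."""
    peak = float(y.max())
    amp_scale = max(peak - baseline0, 1e-12)
    sigma_starts = [s for s in SIGMA_STARTS if s <= window] or [window / 4]

    def model_resid(theta: np.ndarray) -> np.ndarray:
        a = theta[:m]
        s = theta[m : 2 * m]
        c = theta[2 * m]
        pred = c + (a[None, :] * np.exp(-(d[:, None] ** 2) / (2 * s[None, :] ** 2))).sum(axis=1)
        return pred - y

    lb = np.concatenate([np.zeros(m), np.full(m, 1e-8), [0.0]])
    ub = np.concatenate(
        [np.full(m, 10 * amp_scale + 10 * abs(baseline0) + 1e-6), np.full(m, window), [max(peak, 1e-12)]]
    )
    best = None
    for sigma_combo in itertools.combinations(sigma_starts, m) if m <= len(sigma_starts) else [
        tuple(sigma_starts[i % len(sigma_starts)] for i in range(m))
    ]:
        for f in AMPLITUDE_FACTORS:
            x0 = np.concatenate(
                [np.full(m, f * amp_scale), np.asarray(sigma_combo, float), [min(max(baseline0, 0.0), max(peak, 1e-12))]]
            )
            x0 = np.clip(x0, lb, ub)
            try:
                res = least_squares(model_resid, x0, bounds=(lb, ub), max_nfev=50000, xtol=1e-5, ftol=1e-5)
            except Exception:
                continue
            if not res.success:
                continue
            sse = float(np.sum(res.fun**2))
            cand = (res.x[:m].copy(), res.x[m : 2 * m].copy(), float(res.x[2 * m]), sse)
            # ties at equal SSE resolved toward smaller total sigma
            if best is None or sse < best[3] - 1e-15 or (
                abs(sse - best[3]) <= 1e-15 and cand[1].sum() < best[1].sum()
            ):
                best = cand
    return best


def rejection_reason(amplitudes: np.ndarray, sigmas: np.ndarray) -> Optional[str]:
    """Why a fitted component set forces a refit with one fewer curve:
    a zero amplitude, a zero standard deviation, or any component whose
    peak fraction falls below 5% of the summed peaks. Returns None when
    the fit is acceptable."""
    a = np.asarray(amplitudes, dtype=np.float64)
    s = np.asarray(sigmas, dtype=np.float64)
    if np.any(a <= 1e-10):
        return "zero amplitude component"
    if np.any(s <= 1e-6):
        return "zero sigma component"
    contrib = a / a.sum()
    if np.any(contrib < MIN_CONTRIBUTION):
        return f"component contribution < {MIN_CONTRIBUTION}"
    return None


def fit_range_deconvolution(curve: RmsdCurve, max_components: int = 3) -> RangeDeconvolution:
    """Fit y(d) = c + sum_j a_j exp(-d^2 / 2 sigma_j^2) by bounded
    nonlinear least squares with a grid of starting values.

    Fitting starts at m = max_components and falls back to m-1 when any
    of four conditions holds: (i) no start converged, (ii) a component's
    peak fraction is below 5%, (iii) an amplitude is zero, (iv) a sigma
    is zero. A flat curve yields a baseline-only fit with 0 components.
    """
    d = curve.offsets
    y = curve.values
    window = float(np.max(np.abs(d)))
    n_outer = max(1, int(round(d.size * 0.05)))
    outer = np.concatenate([y[:n_outer], y[-n_outer:]])
    baseline0 = float(np.median(outer))
    fallback: List[str] = []

    if float(y.max() - y.min()) < 1e-12:
        return RangeDeconvolution(
            np.empty(0), np.empty(0), float(np.mean(y)), float(np.sum((y - np.mean(y)) ** 2)),
            True, ["flat curve: baseline-only fit"],
        )

    acceptable = {}
    for m in range(max_components, 0, -1):
        fit = _fit_m_components(d, y, m, baseline0, window)
        if fit is None:
            fallback.append(f"m={m}: no converged fit")
            continue
        a, s, c, sse = fit
        order = np.argsort(s)
        a, s = a[order], s[order]
        reason = rejection_reason(a, s)
        if reason is not None:
            fallback.append(f"m={m}: {reason}")
            continue
        acceptable[m] = (a, s, c, sse)

    if acceptable:
        # best SSE wins; near-ties (within 1% relative) resolve toward
        # fewer components — a noiseless curve fits equally well at any
        # m, and the smallest m is the meaningful answer
        best_sse = min(v[3] for v in acceptable.values())
        sst = float(np.sum((y - y.mean()) ** 2))
        tol = 0.01 * best_sse + 1e-9 * sst
        m_sel = min(m for m, v in acceptable.items() if v[3] <= best_sse + tol)
        a, s, c, sse = acceptable[m_sel]
        return RangeDeconvolution(a, s, c, sse, True, fallback)

    # nothing acceptable: baseline-only
    c = float(np.median(y))
    fallback.append("all component counts rejected: baseline-only fit")
    return RangeDeconvolution(np.empty(0), np.empty(0), c, float(np.sum((y - c) ** 2)), False, fallback)


# span cutpoints (bases) for the <3-component fallback labelling; chosen
# between the characteristic short (~14), medium (~72) and long (~474)
# windows on a log scale
FALLBACK_CUTPOINTS = (40.0, 250.0)


@dataclass
class RangeClassAssignment:
    labels: Dict[Tuple[str, int], str]
    method: str  # "clustered" or "cutpoints"


def assign_range_classes(deconvs: Dict[str, RangeDeconvolution]) -> RangeClassAssignment:
    """Label every fitted component short / medium / long.

    All spans are pooled, log2-transformed and Ward-clustered into three
    groups; clusters ordered by mean span give the labels. With fewer
    than 3 distinct spans, fixed log-scale cutpoints are used instead.
    """
    keys: List[Tuple[str, int]] = []
    spans: List[float] = []
    for sample, dec in deconvs.items():
        for j, sp in enumerate(dec.spans):
            keys.append((sample, j))
            spans.append(float(sp))
    spans_arr = np.asarray(spans)
    names = np.array(["short", "medium", "long"])
    if spans_arr.size >= 3 and np.unique(spans_arr).size >= 3:
        Z = linkage(np.log2(spans_arr)[:, None], method="ward")
        raw = fcluster(Z, t=3, criterion="maxclust")
        means = np.array([spans_arr[raw == c].mean() for c in (1, 2, 3)])
        rank = np.argsort(np.argsort(means))
        labels = {k: names[rank[raw[i] - 1]] for i, k in enumerate(keys)}
        return RangeClassAssignment(labels, "clustered")
    lo, hi = FALLBACK_CUTPOINTS
    labels = {}
    for k, sp in zip(keys, spans_arr):
        labels[k] = "short" if sp < lo else ("medium" if sp < hi else "long")
    return RangeClassAssignment(labels, "cutpoints")


def cluster_breakage_samples(
    curves: Dict[str, RmsdCurve],
    n_clusters: int,
    silhouette_range: Optional[Sequence[int]] = None,
) -> Tuple[Dict[str, int], Dict[int, float]]:
    """Ward / Euclidean clustering of RMSD curves across samples.

    Returns (sample -> cluster label, silhouette score per candidate n
    from ``silhouette_range``)."""
    names = sorted(curves)
    if len(names) < n_clusters:
        raise ValueError("fewer samples than clusters")
    grid = curves[names[0]].offsets
    for nm in names:
        if not np.array_equal(curves[nm].offsets, grid):
            raise ValueError("curves must share one offset grid")
    X = np.stack([curves[nm].values for nm in names])
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    sil: Dict[int, float] = {}
    if silhouette_range is not None:
        from sklearn.metrics import silhouette_score

        for n in silhouette_range:
            if 2 <= n < len(names):
                sil[n] = float(silhouette_score(X, fcluster(Z, t=n, criterion="maxclust")))
    return dict(zip(names, labels.tolist())), sil


def random_breakpoint_control(
    genome: GenomeSequence,
    n: int,
    seed: int,
    k: int = 8,
    half_window: int = DEFAULT_HALF_WINDOW,
) -> RmsdCurve:
    """Negative control: uniformly random bonds through the full
    profile -> RMSD pipeline; expected to show no central peak."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo_pad = half_window
    chroms = sorted(genome.sequences)
    sizes = np.array([max(0, genome.lengths[c] - (2 * lo_pad + k)) for c in chroms], dtype=np.int64)
    if sizes.sum() <= 0:
        raise ValueError("genome too small for the requested window")
    per = rng.multinomial(n, sizes / sizes.sum())
    bonds = {}
    for chrom, m, size in zip(chroms, per, sizes):
        if m == 0:
            continue
        m = min(int(m), int(size))
        picks = rng.choice(size, size=m, replace=False) + lo_pad
        bonds[chrom] = picks
    profile = positional_kmer_profile(genome, BreakpointSet(bonds), k=k, half_window=half_window)
    return adjacent_rmsd(profile)
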
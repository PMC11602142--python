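"""Sequence-context features for fragility classification.

Every candidate bond is described by nested windows centred on it:

* short range (default 14 b): the centred octamer, looked up in one or
  more k-mer susceptibility score tables;
* medium range (default 72 b): putative G-quadruplex (PQS) density —
  the G-run motif G_g1 N_x G_g2 N_y G_g3 N_z G_g4 with runs >= 3 and
  loops 1..max_loop, searched together with its C-strand mirror
  (i-motifs) on the same strand;
* long range (default 474 b): G+C content, GC-skew magnitude, raw
  canonical k-mer counts, and score-weighted k-mer sums (k-mer counts
  scaled by their susceptibility z-scores).

All features are strand symmetric: k-mers are canonicalized, the PQS
search covers both motif polarities and the skew enters by magnitude,
so reverse-complementing the input window leaves every feature
unchanged.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._sequence import (
    all_canonical_kmers,
    canonical_code_tables,
    canonical_kmer,
    encode,
    kmer_codes,
)
from .genomic_io import BreakpointSet, GenomeSequence, IntervalSet
from .kmer_fragility import KmerScoreTable


@dataclass(frozen=True)
class RangeConfig:
    """Nested feature windows (bases, even), centred on the bond."""

    short: int = 14
    medium: int = 72
    long: int = 474

    def __post_init__(self) -> None:
        if not (self.short <= self.medium <= self.long):
            raise ValueError("ranges must satisfy short <= medium <= long")
        if any(r % 2 for r in (self.short, self.medium, self.long)):
            raise ValueError("range spans must be even (centred windows)")


@dataclass(frozen=True)
class PQSMotifSpec:
    """G-quadruplex motif: four G-runs of length >= min_run separated by
    loops of 1..max_loop arbitrary bases."""

    min_run: int = 3
    max_loop: int = 7

    def __post_init__(self) -> None:
        if self.min_run < 3:
            raise ValueError("G-run length must be >= 3")
        if self.max_loop < 1:
            raise ValueError("max loop must be >= 1")

    def patterns(self) -> Tuple[re.Pattern, re.Pattern]:
        g, L = self.min_run, self.max_loop
        g_pat = re.compile(rf"(?:G{{{g},}}[ACGT]{{1,{L}}}){{3}}G{{{g},}}")
        c_pat = re.compile(rf"(?:C{{{g},}}[ACGT]{{1,{L}}}){{3}}C{{{g},}}")
        return g_pat, c_pat


def pqs_scan(seq: str, spec: PQSMotifSpec = PQSMotifSpec()) -> Tuple[List[Tuple[int, int]], float]:
    """Leftmost non-overlapping matches of the G-pattern and of the
    C-pattern (i-motif mirror) on the given strand. Returns the match
    intervals and the fraction of bases covered by their union."""
    su = seq.upper()
    intervals: List[Tuple[int, int]] = []
    for pat in spec.patterns():
        intervals.extend(m.span() for m in pat.finditer(su))
    intervals.sort()
    covered = 0
    cur_s = cur_e = None
    merged: List[Tuple[int, int]] = []
    for s, e in intervals:
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    if cur_s is not None:
        merged.append((cur_s, cur_e))
    covered = sum(e - s for s, e in merged)
    density = covered / len(su) if su else 0.0
    return intervals, density


def composition_features(seq: str) -> Tuple[float, float]:
    """(gc_content, gc_skew) with skew defined as [G-C]/[G+C].

    N bases are excluded from both numerator and denominator; an all-N
    sequence yields (0, 0) with a warning. Note the signed skew flips
    under reverse complementation; the feature matrix therefore stores
    its magnitude."""
    if not seq:
        raise ValueError("empty sequence")
    arr = encode(seq)
    g = int((arr == 2).sum())
    c = int((arr == 1).sum())
    valid = int((arr < 4).sum())
    if valid == 0:
        warnings.warn("all-N sequence; composition features set to 0")
        return 0.0, 0.0
    gc = g + c
    content = gc / valid
    skew = (g - c) / gc if gc > 0 else 0.0
    return content, skew


def context_octamer(genome: GenomeSequence, chrom: str, bond: int) -> str:
    """Canonical 8-mer centred on the bond ([bond-4, bond+4))."""
    L = genome.lengths[chrom]
    if bond - 4 < 0 or bond + 4 > L:
        raise ValueError(f"bond {bond} lacks 4-base context on {chrom}")
    return canonical_kmer(genome.fetch(chrom, bond - 4, bond + 4))


def weighted_kmer_counts(seq: str, table: KmerScoreTable) -> float:
    """Sum of the table's z over all sliding canonical k-mers of the
    sequence; windows containing N are skipped."""
    k = table.k
    if k > len(seq):
        raise ValueError("sequence shorter than table k")
    codes = kmer_codes(encode(seq), k)
    canon_index, _ = canonical_code_tables(k)
    z = table.z.to_numpy(dtype=np.float64)
    good = codes >= 0
    return float(z[canon_index[codes[good]]].sum())


class FeatureExtractor:
    """Vectorised feature computation for arrays of bonds on one sequence.

    Column order is deterministic: per score table (sorted by name) the
    context k-mer z and the weighted k-mer sum, then raw canonical
    k-mer counts, then gc_content, gc_skew_mag, pqs_density.
    """

    def __init__(
        self,
        ranges: RangeConfig = RangeConfig(),
        score_tables: Optional[Mapping[str, KmerScoreTable]] = None,
        raw_k: int = 3,
        pqs_spec: PQSMotifSpec = PQSMotifSpec(),
    ) -> None:
        self.ranges = ranges
        self.score_tables = dict(score_tables or {})
        self.raw_k = raw_k
        self.pqs_spec = pqs_spec
        self._raw_vocab = list(all_canonical_kmers(raw_k))
        cols: List[str] = []
        for name in sorted(self.score_tables):
            cols.append(f"ctx_z[{name}]")
            cols.append(f"wsum[{name}]")
        cols.extend(f"count_{km}" for km in self._raw_vocab)
        cols.extend(["gc_content", "gc_skew_mag", "pqs_density"])
        self.columns = cols

    @property
    def context_required(self) -> int:
        return self.ranges.long // 2

    def features_for_bonds(self, seq: str, bonds: np.ndarray) -> np.ndarray:
        bonds = np.asarray(bonds, dtype=np.int64)
        L = len(seq)
        half_long = self.ranges.long // 2
        half_med = self.ranges.medium // 2
        if bonds.size and (bonds.min() < half_long or bonds.max() > L - half_long):
            raise ValueError("bond lacks full long-range context")
        arr = encode(seq)
        out = np.zeros((bonds.size, len(self.columns)), dtype=np.float64)
        col = 0
        for name in sorted(self.score_tables):
            table = self.score_tables[name]
            k = table.k
            canon_index, _ = canonical_code_tables(k)
            z = table.z.to_numpy(dtype=np.float64)
            codes = kmer_codes(arr, k)
            # context k-mer centred on the bond; N windows contribute 0
            start = bonds - k // 2
            ctx = codes[start]
            vals = np.where(ctx >= 0, z[canon_index[np.maximum(ctx, 0)]], 0.0)
            out[:, col] = vals
            # windowed z-weighted k-mer sum over the long range
            zpos = np.zeros(codes.size + 1)
            good = codes >= 0
            zpos[1:][good] = z[canon_index[codes[good]]]
            cs = np.cumsum(zpos)
            w_start = bonds - half_long
            w_end = np.minimum(bonds + half_long - k + 1, codes.size)
            out[:, col + 1] = cs[w_end] - cs[w_start]
            col += 2
        # raw canonical k-mer counts over the long range
        rk = self.raw_k
        canon_index_r, canon_codes_r = canonical_code_tables(rk)
        codes_r = kmer_codes(arr, rk)
        n_raw = canon_codes_r.size
        for i, b in enumerate(bonds):
            w = codes_r[b - half_long : b + half_long - rk + 1]
            w = w[w >= 0]
            if w.size:
                out[i, col : col + n_raw] = np.bincount(canon_index_r[w], minlength=n_raw)
        col += n_raw
        # composition over the long range
        is_g = np.concatenate([[0], (arr == 2).astype(np.int64)]).cumsum()
        is_c = np.concatenate([[0], (arr == 1).astype(np.int64)]).cumsum()
        is_ok = np.concatenate([[0], (arr < 4).astype(np.int64)]).cumsum()
        s, e = bonds - half_long, bonds + half_long
        g = is_g[e] - is_g[s]
        c = is_c[e] - is_c[s]
        ok = is_ok[e] - is_ok[s]
        gc = g + c
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, col] = np.where(ok > 0, gc / ok, 0.0)
            out[:, col + 1] = np.where(gc > 0, np.abs(g - c) / np.maximum(gc, 1), 0.0)
        col += 2
        # PQS density over the medium range
        for i, b in enumerate(bonds):
            _, density = pqs_scan(seq[b - half_med : b + half_med], self.pqs_spec)
            out[i, col] = density
        if not np.isfinite(out).all():
            raise AssertionError("non-finite feature values")
        return out


DEFAULT_CONTROL_CASE_RATIO = 61 / 39  # deliberate class imbalance


def assemble_feature_matrix(
    genome: GenomeSequence,
    breaks: BreakpointSet,
    extractor: FeatureExtractor,
    control_regions: Optional[IntervalSet] = None,
    control_bonds: Optional[BreakpointSet] = None,
    control_case_ratio: float = DEFAULT_CONTROL_CASE_RATIO,
    seed: int = 0,
) -> pd.DataFrame:
    """Labelled feature matrix over break bonds (label 1) and control
    bonds (label 0).

    Controls are taken as given, or sampled uniformly (seeded) from the
    control regions (whole genome when None). Control bonds whose
    medium-range window overlaps any break's medium-range window are
    dropped — long-range overlap is tolerated, as the signal beyond the
    medium span is negligible. Rows are (chrom, bond)-indexed and sorted
    within each class; output is fully deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    ctx = extractor.context_required
    med = extractor.ranges.medium

    case: Dict[str, np.ndarray] = {}
    for chrom in breaks.chroms:
        L = genome.lengths[chrom]
        b = breaks.bonds[chrom]
        case[chrom] = b[(b >= ctx) & (b <= L - ctx)]
    n_case = sum(v.size for v in case.values())
    if n_case == 0:
        raise ValueError("no break bonds with full context")

    def _far_from_breaks(chrom: str, cb: np.ndarray) -> np.ndarray:
        """Keep bonds whose medium window cannot overlap any break's."""
        bb = breaks.bonds.get(chrom, np.empty(0, dtype=np.int64))
        if bb.size == 0 or cb.size == 0:
            return cb
        idx = np.searchsorted(bb, cb)
        dist = np.full(cb.shape, np.iinfo(np.int64).max)
        left_ok = idx > 0
        dist[left_ok] = np.minimum(dist[left_ok], cb[left_ok] - bb[idx[left_ok] - 1])
        right_ok = idx < bb.size
        dist[right_ok] = np.minimum(
            dist[right_ok], bb[np.minimum(idx[right_ok], bb.size - 1)] - cb[right_ok]
        )
        return cb[dist >= med]

    if control_bonds is None:
        n_ctrl = int(round(n_case * control_case_ratio))
        candidates: List[Tuple[str, np.ndarray]] = []
        if control_regions is None:
            for chrom in sorted(genome.sequences):
                L = genome.lengths[chrom]
                if L >= 2 * ctx:
                    candidates.append((chrom, np.arange(ctx, L - ctx + 1)))
        else:
            for iv in control_regions:
                L = genome.lengths[iv.chrom]
                lo, hi = max(iv.start, ctx), min(iv.end, L - ctx)
                if lo < hi:
                    candidates.append((iv.chrom, np.arange(lo, hi)))
        candidates = [(c, _far_from_breaks(c, a)) for c, a in candidates]
        pool_chrom = np.concatenate(
            [np.full(a.size, i) for i, (_, a) in enumerate(candidates)]
        )
        pool_bond = np.concatenate([a for _, a in candidates])
        take = min(n_ctrl, pool_bond.size)
        picks = rng.choice(pool_bond.size, size=take, replace=False)
        ctrl: Dict[str, List[int]] = {}
        for p in picks:
            ctrl.setdefault(candidates[pool_chrom[p]][0], []).append(int(pool_bond[p]))
        control = {c: np.asarray(v) for c, v in ctrl.items()}
    else:
        control = {}
        for chrom, b in control_bonds.bonds.items():
            L = genome.lengths[chrom]
            cb = np.unique(b)
            cb = cb[(cb >= ctx) & (cb <= L - ctx)]
            control[chrom] = _far_from_breaks(chrom, cb)

    n_ctrl_final = sum(v.size for v in control.values())
    if n_ctrl_final == 0:
        raise ValueError("no control bonds left after overlap removal")

    frames = []
    for label, bond_map in ((1, case), (0, control)):
        for chrom in sorted(bond_map):
            b = np.sort(bond_map[chrom])
            if b.size == 0:
                continue
            X = extractor.features_for_bonds(genome.sequences[chrom], b)
            df = pd.DataFrame(X, columns=extractor.columns)
            df.insert(0, "chrom", chrom)
            df.insert(1, "bond", b)
            df["label"] = label
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out = out.set_index(["chrom", "bond"])
    return out
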
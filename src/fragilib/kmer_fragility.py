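"""Per-k-mer intrinsic breakage susceptibility scores.

The population of k-mers found at broken sites (case) is compared with a
negative control population sampled away from breakage regions. Writing
X_i for the case count of canonical k-mer i, n for the total case count
and p_i for the k-mer's control proportion, the susceptibility score is
the one-sample proportion z

    z_i = (X_i - n p_i) / sqrt(n p_i (1 - p_i))

with z > 1 marking susceptible and z < -1 marking resistant k-mers. A
Bayes posterior break probability is available as

    P(break | kmer) = P(break) P(kmer | break) / P(kmer)

where P(kmer) is the control relative frequency and P(kmer | break) the
case relative frequency. k-mers with insufficient counts for the normal
approximation are imputed from the mean z of their five nearest
neighbours by sequence similarity (Hamming distance over both strand
alignments of the canonical forms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from ._sequence import (
    all_canonical_kmers,
    canonical_code_tables,
    canonical_kmer,
    encode,
    kmer_codes,
    revcomp,
)
from .genomic_io import BreakpointSet, GenomeSequence, Interval, IntervalSet

MIN_EXPECTED_COUNT = 5.0  # normal-approximation validity rule
N_IMPUTATION_DONORS = 5

SCORE_TABLE_COLUMNS = ["kmer", "z", "p_control", "p_break_given_kmer", "imputed"]


@dataclass
class KmerCountVector:
    """Counts over the full canonical k-mer vocabulary."""

    k: int
    role: str  # "case" or "control"
    counts: pd.Series  # index: canonical k-mers (lexicographic), values >= 0

    def __post_init__(self) -> None:
        vocab = list(all_canonical_kmers(self.k))
        self.counts = self.counts.reindex(vocab, fill_value=0).astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative k-mer counts")
        if self.role == "case" and self.counts.sum() <= 0:
            raise ValueError("case count vector must have positive total")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_array(cls, k: int, role: str, arr: np.ndarray) -> "KmerCountVector":
        return cls(k, role, pd.Series(arr, index=list(all_canonical_kmers(k))))


def count_kmers_in_regions(
    genome: GenomeSequence, regions: IntervalSet, k: int, role: str = "control"
) -> KmerCountVector:
    """Canonical k-mer counts over all sliding windows inside the
    regions; windows containing N are skipped."""
    canon_index, canon_codes = canonical_code_tables(k)
    acc = np.zeros(canon_codes.size, dtype=np.int64)
    for iv in regions:
        if iv.end - iv.start < k:
            continue
        codes = kmer_codes(encode(genome.fetch(iv.chrom, iv.start, iv.end)), k)
        codes = codes[codes >= 0]
        if codes.size:
            acc += np.bincount(canon_index[codes], minlength=canon_codes.size)
    return KmerCountVector.from_array(k, role, acc)


def count_breakpoint_kmers(
    genome: GenomeSequence, breaks: BreakpointSet, k: int, role: str = "case"
) -> KmerCountVector:
    """Canonical k-mer centred on each bond ([b - k//2, b + k - k//2));
    bonds without full context or with N in the window are skipped."""
    canon_index, canon_codes = canonical_code_tables(k)
    acc = np.zeros(canon_codes.size, dtype=np.int64)
    left = k // 2
    for chrom in breaks.chroms:
        bonds = breaks.bonds[chrom]
        L = genome.lengths[chrom]
        ok = (bonds - left >= 0) & (bonds - left + k <= L)
        bonds = bonds[ok]
        if bonds.size == 0:
            continue
        codes = kmer_codes(encode(genome.sequences[chrom]), k)
        c = codes[bonds - left]
        c = c[c >= 0]
        if c.size:
            acc += np.bincount(canon_index[c], minlength=canon_codes.size)
    return KmerCountVector.from_array(k, role, acc)


def build_control_regions(
    break_regions: IntervalSet,
    genome: GenomeSequence,
    long_span: Optional[float] = None,
) -> IntervalSet:
    """Construct control flanks beyond the reach of sequence influence.

    The flank width w is the long-range influence span plus 1 kb when a
    span is known, otherwise the mean length of the top 5% longest
    merged breakage regions. Controls are the windows [s-2w, s-w) and
    [e+w, e+2w) around each breakage region [s, e), clipped to the
    chromosome, with any overlap with breakage regions removed.
    """
    merged = break_regions.merge()
    if long_span is not None:
        width = int(round(long_span + 1000))
    else:
        lengths = sorted((len(iv) for iv in merged), reverse=True)
        if not lengths:
            raise ValueError("no breakage regions")
        n_top = max(1, int(round(0.05 * len(lengths))))
        width = int(round(float(np.mean(lengths[:n_top]))))
    out: List[Interval] = []
    for iv in merged:
        L = genome.lengths[iv.chrom]
        for s, e in ((iv.start - 2 * width, iv.start - width), (iv.end + width, iv.end + 2 * width)):
            s, e = max(0, s), min(L, e)
            if s >= e:
                warnings.warn(
                    f"control flank for {iv.chrom}:[{iv.start},{iv.end}) exceeds chromosome; dropped"
                )
                continue
            out.append(Interval(iv.chrom, s, e))
    return IntervalSet(out).merge().subtract(merged)


@dataclass
class KmerScoreTable:
    """Canonical k-mer scores with provenance metadata.

    ``data`` is indexed by canonical k-mer with columns: z, p_control,
    p_case, p_break_given_kmer, imputed (bool), insufficient (bool).
    """

    k: int
    data: pd.DataFrame
    n_case: int = 0
    n_control: int = 0
    source: str = ""
    control_spec: str = ""
    prior_p_break: Optional[float] = None

    @property
    def z(self) -> pd.Series:
        return self.data["z"]

    def __len__(self) -> int:
        return len(self.data)


def fragility_zscores(case: KmerCountVector, control: KmerCountVector) -> KmerScoreTable:
    """One-sample proportion z per canonical k-mer: case counts against
    control proportions.

    k-mers whose expected counts violate the normal approximation
    (min(n p_i, n (1 - p_i)) < 5, or p_i = 0) are flagged insufficient
    and left NaN for imputation.
    """
    if case.k != control.k:
        raise ValueError(f"k mismatch: case k={case.k}, control k={control.k}")
    if control.total <= 0:
        raise ValueError("control total must be positive")
    X = case.counts.to_numpy(dtype=np.float64)
    n = float(case.total)
    p = control.counts.to_numpy(dtype=np.float64) / control.total
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (X - n * p) / np.sqrt(n * p * (1.0 - p))
    insufficient = (p <= 0) | (np.minimum(n * p, n * (1.0 - p)) < MIN_EXPECTED_COUNT)
    z = np.where(insufficient, np.nan, z)
    df = pd.DataFrame(
        {
            "z": z,
            "p_control": p,
            "p_case": X / n,
            "p_break_given_kmer": np.nan,
            "imputed": False,
            "insufficient": insufficient,
        },
        index=case.counts.index,
    )
    return KmerScoreTable(case.k, df, n_case=case.total, n_control=control.total)


def break_probability(table: KmerScoreTable, prior_p_break: Optional[float] = None) -> KmerScoreTable:
    """Bayes posterior P(break | kmer) = prior * p_case / p_control,
    clipped to [0, 1] with a warning when the likelihood ratio exceeds
    the 1/prior bound. The default prior is n_case/(n_case+n_control).
    k-mers with p_control = 0 but observed in the case are routed to the
    imputation path (flagged insufficient)."""
    if prior_p_break is None:
        prior_p_break = table.n_case / (table.n_case + table.n_control)
    if not (0.0 < prior_p_break < 1.0):
        raise ValueError("prior P(break) must be in (0, 1)")
    df = table.data
    p_ctrl = df["p_control"].to_numpy()
    p_case = df["p_case"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        post = prior_p_break * p_case / p_ctrl
    zero_ctrl = (p_ctrl <= 0) & (p_case > 0)
    if zero_ctrl.any():
        df.loc[zero_ctrl, "insufficient"] = True
    post = np.where(p_ctrl <= 0, np.nan, post)
    if np.nanmax(post, initial=0.0) > 1.0:
        warnings.warn("posterior exceeded 1 for some k-mers; clipped to [0, 1]")
    df["p_break_given_kmer"] = np.clip(post, 0.0, 1.0)
    table.prior_p_break = float(prior_p_break)
    return table


def _hamming_matrix(targets: np.ndarray, donors_fwd: np.ndarray, donors_rc: np.ndarray) -> np.ndarray:
    """min over strand alignments of per-position mismatch counts;
    targets (t, k) against donors (d, k) -> (t, d)."""
    fwd = (targets[:, None, :] != donors_fwd[None, :, :]).sum(axis=2)
    rc = (targets[:, None, :] != donors_rc[None, :, :]).sum(axis=2)
    return np.minimum(fwd, rc)


def impute_sparse_kmers(table: KmerScoreTable) -> KmerScoreTable:
    """Fill every insufficient k-mer with the mean z of its 5 nearest
    non-imputed donors by sequence similarity (Hamming distance, min
    over the two strand alignments; ties broken lexicographically).
    Falls back to the global donor mean with a warning when fewer than
    5 donors exist. Non-flagged entries are never modified."""
    df = table.data
    flagged = df.index[df["insufficient"] & df["z"].isna()]
    donors = df.index[~df["insufficient"]]
    if len(flagged) == 0:
        return table
    if len(donors) < N_IMPUTATION_DONORS:
        warnings.warn("fewer than 5 donors; global mean fallback for imputation")
        fill = float(df.loc[donors, "z"].mean()) if len(donors) else 0.0
        df.loc[flagged, "z"] = fill
        df.loc[flagged, "imputed"] = True
        return table
    donor_z = df.loc[donors, "z"].to_numpy()
    donors_fwd = np.stack([encode(s) for s in donors])
    donors_rc = np.stack([encode(revcomp(s)) for s in donors])
    # donors are already lexicographically sorted (table index order),
    # so a stable sort on distance realises the tie rule
    chunk = 1024
    flagged_list = list(flagged)
    for i0 in range(0, len(flagged_list), chunk):
        batch = flagged_list[i0 : i0 + chunk]
        tmat = np.stack([encode(s) for s in batch])
        dist = _hamming_matrix(tmat, donors_fwd, donors_rc)
        order = np.argsort(dist, axis=1, kind="stable")[:, :N_IMPUTATION_DONORS]
        df.loc[batch, "z"] = donor_z[order].mean(axis=1)
    df.loc[flagged, "imputed"] = True
    return table


def write_score_table(table: KmerScoreTable, path) -> None:
    """Score-table TSV interchange format: kmer, z, p_control,
    p_break_given_kmer, imputed."""
    out = pd.DataFrame(
        {
            "kmer": table.data.index,
            "z": table.data["z"].to_numpy(),
            "p_control": table.data["p_control"].to_numpy(),
            "p_break_given_kmer": table.data["p_break_given_kmer"].to_numpy(),
            "imputed": table.data["imputed"].astype(int).to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_score_table(path) -> KmerScoreTable:
    raw = pd.read_csv(path, sep="\t")
    missing = [c for c in SCORE_TABLE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    k = len(raw["kmer"].iloc[0])
    df = pd.DataFrame(
        {
            "z": raw["z"].to_numpy(),
            "p_control": raw["p_control"].to_numpy(),
            "p_case": np.nan,
            "p_break_given_kmer": raw["p_break_given_kmer"].to_numpy(),
            "imputed": raw["imputed"].astype(bool).to_numpy(),
            "insufficient": False,
        },
        index=raw["kmer"].tolist(),
    )
    return KmerScoreTable(k, df, source=str(path))


@dataclass
class ClusteredScores:
    matrix: pd.DataFrame  # standardized, samples x k-mers
    row_order: List[str]
    col_order: List[str]
    row_labels: Dict[str, int]


def normalize_and_cluster(
    tables: Mapping[str, KmerScoreTable], n_clusters: int = 2
) -> ClusteredScores:
    """Standardize each sample's scores (mean 0, sd 1) and Ward-cluster
    both samples and k-mers; constant tables are excluded with a
    warning. Returns the heatmap-ready matrix with dendrogram orders."""
    rows = {}
    for name, t in tables.items():
        z = t.z
        if float(z.std(ddof=0)) == 0.0 or z.isna().all():
            warnings.warn(f"table {name!r} is constant; excluded from clustering")
            continue
        rows[name] = (z - z.mean()) / z.std(ddof=0)
    if len(rows) < 2:
        raise ValueError("need at least 2 non-constant tables")
    mat = pd.DataFrame(rows).T
    mat = mat.dropna(axis=1)
    Zr = linkage(mat.to_numpy(), method="ward")
    Zc = linkage(mat.to_numpy().T, method="ward")
    row_order = [mat.index[i] for i in leaves_list(Zr)]
    col_order = [mat.columns[i] for i in leaves_list(Zc)]
    labels = fcluster(Zr, t=n_clusters, criterion="maxclust")
    return ClusteredScores(mat, row_order, col_order, dict(zip(mat.index, labels.tolist())))


@dataclass
class OutlierComparison:
    delta: pd.Series  # mean_A(z) - mean_B(z) per k-mer
    resistant: List[str]  # bottom 0.5% of delta
    susceptible: List[str]  # top 0.5% of delta
    energy_summary: Optional[pd.DataFrame]
    t_statistic: float
    p_value: float


def hybridization_energy(kmer: str, triplet_table: Mapping[str, float]) -> float:
    """Mean of the overlapping triplet hybridization energies along the
    k-mer (one-nucleotide sliding window)."""
    if len(kmer) < 3:
        raise ValueError("k-mer must have length >= 3")
    vals = []
    for i in range(len(kmer) - 2):
        t = kmer[i : i + 3]
        if t not in triplet_table:
            raise KeyError(f"triplet {t!r} missing from table")
        vals.append(float(triplet_table[t]))
    return float(np.mean(vals))


def outlier_kmer_sets(
    tables_a: Sequence[KmerScoreTable],
    tables_b: Sequence[KmerScoreTable],
    triplet_table: Optional[Mapping[str, float]] = None,
) -> OutlierComparison:
    """Mean z difference between two sample groups per k-mer; the top 1%
    most extreme k-mers (0.5% each side) form the susceptible and
    resistant sets, compared by a two-sample t-test (on hybridization
    energies when a triplet table is supplied, otherwise on the deltas).
    """
    ks = {t.k for t in tables_a} | {t.k for t in tables_b}
    if len(ks) != 1:
        raise ValueError("all tables must share one k")
    mean_a = pd.concat([t.z for t in tables_a], axis=1).mean(axis=1)
    mean_b = pd.concat([t.z for t in tables_b], axis=1).mean(axis=1)
    delta = (mean_a - mean_b).dropna()
    n = len(delta)
    if n < 200:
        raise ValueError("need >= 200 k-mers for 0.5% tails")
    n_tail = max(1, int(np.ceil(0.005 * n)))
    ordered = delta.sort_values(kind="stable")
    resistant = ordered.index[:n_tail].tolist()
    susceptible = ordered.index[-n_tail:].tolist()
    if triplet_table is not None:
        e_res = np.array([hybridization_energy(s, triplet_table) for s in resistant])
        e_sus = np.array([hybridization_energy(s, triplet_table) for s in susceptible])
        t_stat, p = stats.ttest_ind(e_sus, e_res)
        summary = pd.DataFrame(
            {
                "set": ["resistant", "susceptible"],
                "mean_energy": [e_res.mean(), e_sus.mean()],
                "sd_energy": [e_res.std(ddof=1), e_sus.std(ddof=1)],
            }
        )
    else:
        t_stat, p = stats.ttest_ind(delta[susceptible], delta[resistant])
        summary = None
    return OutlierComparison(delta, resistant, susceptible, summary, float(t_stat), float(p))


def score_correlation_network(
    tables: Mapping[str, KmerScoreTable], min_abs_r: float = 0.7
) -> List[Tuple[str, str, float]]:
    """Pearson correlation of z profiles across tables on the shared
    canonical k-mers; zero-variance tables are excluded; self edges are
    removed; only edges with |r| >= min_abs_r are kept (signed)."""
    if len(tables) < 2:
        raise ValueError("need at least 2 tables")
    usable = {}
    for name, t in tables.items():
        z = t.z.dropna()
        if float(z.std(ddof=0)) == 0.0:
            warnings.warn(f"table {name!r} has zero variance; excluded")
            continue
        usable[name] = z
    names = sorted(usable)
    edges = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = usable[a].index.intersection(usable[b].index)
            if len(shared) < 3:
                continue
            r = float(np.corrcoef(usable[a][shared], usable[b][shared])[0, 1])
            if abs(r) >= min_abs_r:
                edges.append((a, b, r))
    return edges
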
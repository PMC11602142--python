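"""Seeded synthetic genomes and breakpoint sets with planted
sequence-driven fragility.

The generator emulates the structure the analysis is designed to
detect: every canonical octamer carries a planted relative breakage
propensity, and a bond's breakage probability is a baseline plus a
mixture of Gaussian-enveloped averages of the surrounding octamer
propensities — one envelope per range of influence (short / medium /
long, default sigmas 3 / 30 / 200 bases with mixing weights
0.6 / 0.3 / 0.1). Breakpoints are sampled without replacement (a bond
breaks at most once per dataset). All randomness flows through one
seeded generator passed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._sequence import all_canonical_kmers, canonical_code_tables, encode, kmer_codes
from .genomic_io import BreakpointSet, GenomeSequence
from .kmer_fragility import KmerCountVector

DEFAULT_SIGMAS = (3.0, 30.0, 200.0)
DEFAULT_WEIGHTS = (0.6, 0.3, 0.1)
DEFAULT_BASELINE = 0.2
DEFAULT_GC = 0.41  # human-like genomic GC fraction


@dataclass
class FragilityGroundTruth:
    """Planted per-octamer breakage propensities and range envelopes."""

    propensity: pd.Series  # canonical octamer -> relative propensity (> 0)
    sigmas: Tuple[float, ...] = DEFAULT_SIGMAS
    weights: Tuple[float, ...] = DEFAULT_WEIGHTS
    baseline: float = DEFAULT_BASELINE
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.propensity <= 0).any():
            raise ValueError("propensities must be positive")
        w = np.asarray(self.weights, dtype=np.float64)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if len(self.sigmas) != len(self.weights):
            raise ValueError("sigmas and weights must align")

    @classmethod
    def random(
        cls,
        seed: int,
        effect_sd: float = 1.0,
        sigmas: Tuple[float, ...] = DEFAULT_SIGMAS,
        weights: Tuple[float, ...] = DEFAULT_WEIGHTS,
        baseline: float = DEFAULT_BASELINE,
    ) -> "FragilityGroundTruth":
        """Log-normal propensities: exp(N(0, effect_sd)) per canonical
        octamer. effect_sd = 0 plants no signal (negative control)."""
        rng = np.random.default_rng(seed)
        vocab = list(all_canonical_kmers(8))
        prop = np.exp(rng.normal(0.0, effect_sd, size=len(vocab))) if effect_sd > 0 else np.ones(len(vocab))
        return cls(pd.Series(prop, index=vocab), sigmas, weights, baseline, seed)

    @classmethod
    def null(cls, seed: int = 0) -> "FragilityGroundTruth":
        return cls.random(seed, effect_sd=0.0)

    @classmethod
    def motif(
        cls,
        motif: str,
        boost: float = 1000.0,
        sigmas: Tuple[float, ...] = (3.0,),
        weights: Tuple[float, ...] = (1.0,),
        baseline: float = DEFAULT_BASELINE,
        seed: int = 0,
    ) -> "FragilityGroundTruth":
        """Fixed-motif preference: octamers containing the motif (or its
        reverse complement) at any position get ``boost``-fold
        propensity; all others are 1. The sharp positive control for
        the RMSD peak."""
        from ._sequence import revcomp as _rc

        vocab = list(all_canonical_kmers(8))
        m = motif.upper()
        mr = _rc(m)
        hits = np.array(
            [1.0 + (boost - 1.0) * ((m in km or mr in km) or (m in _rc(km) or mr in _rc(km))) for km in vocab]
        )
        return cls(pd.Series(hits, index=vocab), sigmas, weights, baseline, seed)


def simulate_genome(length: int, gc: float = DEFAULT_GC, seed: int = 0) -> GenomeSequence:
    """I.i.d. random genome with P(G) = P(C) = gc/2 on one chromosome
    named 'chrS'."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 <= gc < 1.0) and gc != 0.0:
        raise ValueError("gc must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(4, size=length, p=p)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return GenomeSequence({"chrS": lut[arr].tobytes().decode("ascii")})


def _bond_probabilities(seq: str, truth: FragilityGroundTruth) -> np.ndarray:
    """Unnormalised breakage probability per bond: baseline plus the
    weighted Gaussian-smoothed planted octamer propensity track. The
    octamer at track position b is the one centred on bond b."""
    arr = encode(seq)
    codes = kmer_codes(arr, 8)
    canon_index, _ = canonical_code_tables(8)
    prop = truth.propensity.to_numpy(dtype=np.float64)
    track = np.full(codes.size, prop.mean())
    good = codes >= 0
    track[good] = prop[canon_index[codes[good]]]
    # bond b <-> octamer starting at b-4; valid bonds are 4..len(seq)-4
    out = np.full(len(seq) + 1, 0.0)
    mix = np.zeros_like(track)
    for sigma, w in zip(truth.sigmas, truth.weights):
        if sigma > 0:
            mix += w * gaussian_filter1d(track, sigma=sigma, mode="nearest")
        else:  # short-range limit: the bond's own octamer decides
            mix += w * track
    out[4 : 4 + codes.size] = truth.baseline + mix
    return out


def simulate_breakpoints(
    genome: GenomeSequence, truth: FragilityGroundTruth, n: int, seed: int
) -> BreakpointSet:
    """Sample n bonds without replacement with probability proportional
    to the planted model (Gumbel top-k; exact for sampling without
    replacement proportional to weights)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    bonds = {}
    chroms = sorted(genome.sequences)
    lengths = np.array([genome.lengths[c] for c in chroms], dtype=np.float64)
    per = rng.multinomial(n, lengths / lengths.sum()) if len(chroms) > 1 else [n]
    for chrom, m in zip(chroms, per):
        if m == 0:
            continue
        seq = genome.sequences[chrom]
        w = _bond_probabilities(seq, truth)
        valid = np.flatnonzero(w > 0)
        valid = valid[(valid > 0) & (valid < len(seq))]
        if m > valid.size:
            raise ValueError(f"n exceeds candidate bonds on {chrom}")
        keys = np.log(w[valid]) + rng.gumbel(size=valid.size)
        top = np.argpartition(keys, -m)[-m:]
        bonds[chrom] = np.sort(valid[top])
    return BreakpointSet(bonds)


def background_octamer_frequencies(genome: GenomeSequence) -> pd.Series:
    """Canonical octamer relative frequencies across the genome."""
    canon_index, canon_codes = canonical_code_tables(8)
    acc = np.zeros(canon_codes.size, dtype=np.int64)
    for chrom in sorted(genome.sequences):
        codes = kmer_codes(encode(genome.sequences[chrom]), 8)
        codes = codes[codes >= 0]
        acc += np.bincount(canon_index[codes], minlength=canon_codes.size)
    freq = acc / acc.sum()
    return pd.Series(freq, index=list(all_canonical_kmers(8)))


def simulate_count_tables(
    truth: FragilityGroundTruth,
    n_case: int,
    n_control: int,
    seed: int,
    background: Optional[pd.Series] = None,
) -> Tuple[KmerCountVector, KmerCountVector]:
    """Paired case/control canonical-octamer count tables: control is
    multinomial from the background octamer distribution (uniform when
    none given), case from background times planted propensity,
    renormalised."""
    if n_case <= 0 or n_control <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    vocab = list(all_canonical_kmers(8))
    if background is None:
        bg = np.full(len(vocab), 1.0 / len(vocab))
    else:
        bg = background.reindex(vocab).to_numpy(dtype=np.float64)
        bg = bg / bg.sum()
    prop = truth.propensity.reindex(vocab).to_numpy(dtype=np.float64)
    case_p = bg * prop
    case_p = case_p / case_p.sum()
    case = rng.multinomial(n_case, case_p)
    control = rng.multinomial(n_control, bg)
    return (
        KmerCountVector.from_array(8, "case", case),
        KmerCountVector.from_array(8, "control", control),
    )
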
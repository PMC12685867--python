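"""Protein sequence descriptors: nine families, 1,103 features per sequence.

The families, their dimensionalities and their order in the schema are

======================  ======  ==============================================
family                  dims    content
======================  ======  ==============================================
AAC (``aac_*``)         20      amino-acid composition
DC (``dipep_*``)        400     dipeptide (adjacent-pair) composition
PseAAC (``pseudo_*``)   30      type-1 pseudo amino-acid composition, lambda=10
APseAAC                 40      type-2 (amphiphilic) pseudo composition,
(``amphipseudo_*``)             lambda=10, two scales
CTD (``comp_/tran_/     147     7 physicochemical properties x 3 groups:
dist_*``)                       composition (21), transition (21),
                                distribution quantiles (105)
SS (``ss_*``)           6       helix/strand/coil fractions + longest runs
SOCN (``socn_*``)       20      sequence-order coupling numbers, lags 1..20
QSO (``qso_*``)         40      quasi-sequence-order (composition + coupling)
PSSM (``pssm_*``)       400     logistic-squashed PSSM transition scores
======================  ======  ==============================================

All families index residues in the canonical ``ARNDCQEGHILKMFPSTWYV`` order,
so ``aac_5`` is cysteine composition and ``dist_93`` is the 50% positional
quantile of the buried group of the solvent-accessibility property.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._alphabet import AA_INDEX
from ._tables import (
    CTD_GROUP_OF,
    PAAC_SCALES,
    SS_PROPENSITY,
    blosum62_rows,
    physicochemical_distance_matrix,
)
from .schema import SCHEMA_VERSION, FeatureMatrix, FeatureSchema
from .seqio import ProteinSequence, PSSMProfile, SecondaryStructureString

__all__ = [
    "DescriptorParams",
    "extract_aac",
    "extract_dc",
    "extract_paac",
    "extract_apaac",
    "extract_ctd",
    "extract_ss",
    "extract_socn",
    "extract_qso",
    "extract_pssm_transition",
    "featurize",
]


class ShortSequenceError(ValueError):
    """Sequence shorter than a descriptor's lag requirement."""


@dataclass(frozen=True)
class DescriptorParams:
    """Tunable descriptor parameters.

    The lags are pinned by the printed family dimensionalities
    (30 = 20 + lambda_paac, 40 = 20 + 2*lambda_apaac, 20 coupling lags,
    40 = 20 + 20 for QSO); the weights are the conventional defaults.
    """

    lambda_paac: int = 10
    lambda_apaac: int = 10
    w_paac: float = 0.05
    w_apaac: float = 0.05
    maxlag_so: int = 20
    w_qso: float = 0.1

    def __post_init__(self) -> None:
        if self.lambda_paac < 1 or self.lambda_apaac < 1 or self.maxlag_so < 1:
            raise ValueError("lags must be positive")


_DIST = physicochemical_distance_matrix()
_BLOSUM = None  # lazy: biopython load deferred until first use


def _encode(seq: ProteinSequence) -> np.ndarray:
    return np.fromiter((AA_INDEX[c] for c in seq.residues), dtype=np.int64,
                       count=len(seq.residues))


def extract_aac(seq: ProteinSequence) -> np.ndarray:
    """Amino-acid composition: count(r)/L for each of the 20 residues."""
    idx = _encode(seq)
    return np.bincount(idx, minlength=20) / len(idx)


def extract_dc(seq: ProteinSequence) -> np.ndarray:
    """Dipeptide composition: adjacent-pair counts / (L-1), row-major 20x20."""
    idx = _encode(seq)
    if len(idx) < 2:
        raise ShortSequenceError(f"{seq.id!r}: dipeptide composition needs L >= 2")
    pairs = idx[:-1] * 20 + idx[1:]
    return np.bincount(pairs, minlength=400) / (len(idx) - 1)


def _paac_correlations(idx: np.ndarray, lam: int) -> np.ndarray:
    """Type-1 correlation factors tau_1..tau_lam.

    tau_j averages, over positions i, the mean squared difference of the
    three standardized scales between residues j apart.
    """
    props = PAAC_SCALES[:, idx]  # 3 x L
    taus = np.empty(lam)
    for j in range(1, lam + 1):
        d = props[:, j:] - props[:, :-j]
        taus[j - 1] = np.mean(d**2)
    return taus


def extract_paac(seq: ProteinSequence, params: DescriptorParams = DescriptorParams()) -> np.ndarray:
    """Type-1 pseudo amino-acid composition (20 + lambda components, sum 1)."""
    idx = _encode(seq)
    lam, w = params.lambda_paac, params.w_paac
    if len(idx) <= lam:
        raise ShortSequenceError(
            f"{seq.id!r}: PseAAC with lambda={lam} needs L > {lam}, got L={len(idx)}"
        )
    freqs = np.bincount(idx, minlength=20) / len(idx)
    taus = _paac_correlations(idx, lam)
    denom = freqs.sum() + w * taus.sum()
    return np.concatenate([freqs / denom, w * taus / denom])


def _apaac_correlations(idx: np.ndarray, lam: int) -> np.ndarray:
    """Amphiphilic correlation factors: per lag, one hydrophobicity and one
    hydrophilicity squared-difference term, interleaved (2*lam values)."""
    h1 = PAAC_SCALES[0, idx]
    h2 = PAAC_SCALES[1, idx]
    out = np.empty(2 * lam)
    for j in range(1, lam + 1):
        out[2 * (j - 1)] = np.mean((h1[:-j] - h1[j:]) ** 2)
        out[2 * (j - 1) + 1] = np.mean((h2[:-j] - h2[j:]) ** 2)
    return out


def extract_apaac(seq: ProteinSequence, params: DescriptorParams = DescriptorParams()) -> np.ndarray:
    """Amphiphilic pseudo amino-acid composition, 20 + 2*lambda dims.

    Like type-1 PseAAC but with the hydrophobicity and hydrophilicity scales
    tracked separately (interleaved per lag) rather than averaged, so the
    amphiphilic pattern of the two scales is preserved.  All components are
    non-negative and sum to 1; a homopolymer has a zero correlation tail.
    """
    idx = _encode(seq)
    lam, w = params.lambda_apaac, params.w_apaac
    if len(idx) <= lam:
        raise ShortSequenceError(
            f"{seq.id!r}: APseAAC with lambda={lam} needs L > {lam}, got L={len(idx)}"
        )
    freqs = np.bincount(idx, minlength=20) / len(idx)
    taus = _apaac_correlations(idx, lam)
    denom = freqs.sum() + w * taus.sum()
    return np.concatenate([freqs / denom, w * taus / denom])


# -- CTD ---------------------------------------------------------------------

_QUANTILES = (0.0, 0.25, 0.50, 0.75, 1.0)  # 0.0 means "first occurrence"


def extract_ctd(seq: ProteinSequence) -> np.ndarray:
    """Composition/transition/distribution features (21 + 21 + 105 = 147).

    For each of the 7 properties with 3 residue groups:

    * composition C(g)  = occurrences of group g / L
    * transition T(g,h) = (# adjacent gh + hg pairs) / (L-1), pairs ordered
      (1,2), (1,3), (2,3)
    * distribution D(g,q): position (1-based, as a percentage of L) of the
      ceil(q*k)-th occurrence of group g, q in {first, 25%, 50%, 75%, 100%};
      an absent group contributes zeros.
    """
    idx = _encode(seq)
    L = len(idx)
    if L < 2:
        raise ShortSequenceError(f"{seq.id!r}: CTD needs L >= 2")
    comp = np.zeros((7, 3))
    tran = np.zeros((7, 3))
    dist = np.zeros((7, 3, 5))
    for p in range(7):
        g = CTD_GROUP_OF[p, idx]  # group id per position
        counts = np.bincount(g, minlength=3)
        comp[p] = counts / L
        a, b = g[:-1], g[1:]
        for t, (x, y) in enumerate(((0, 1), (0, 2), (1, 2))):
            tran[p, t] = np.sum(((a == x) & (b == y)) | ((a == y) & (b == x))) / (L - 1)
        for grp in range(3):
            pos = np.flatnonzero(g == grp) + 1  # 1-based
            k = len(pos)
            if k == 0:
                continue
            for qi, q in enumerate(_QUANTILES):
                rank = 1 if q == 0.0 else math.ceil(q * k)
                dist[p, grp, qi] = 100.0 * pos[rank - 1] / L
    return np.concatenate([comp.ravel(), tran.ravel(), dist.ravel()])


# -- secondary structure -----------------------------------------------------

def predict_ss_fallback(seq: ProteinSequence) -> SecondaryStructureString:
    """Propensity-based three-state prediction used when no .ss2 is supplied.

    Per-residue helix/strand/coil propensities are smoothed with a centered
    moving average of window 5, then the argmax state is taken.  This is a
    deliberately simple internal stand-in; externally predicted profiles
    take precedence when provided.
    """
    idx = _encode(seq)
    scores = SS_PROPENSITY[:, idx]  # 3 x L
    L = scores.shape[1]
    smoothed = np.empty_like(scores)
    half = 2
    for i in range(L):
        lo, hi = max(0, i - half), min(L, i + half + 1)
        smoothed[:, i] = scores[:, lo:hi].mean(axis=1)
    states = "".join("HEC"[k] for k in smoothed.argmax(axis=0))
    return SecondaryStructureString(sequence_id=seq.id, states=states)


def extract_ss(seq: ProteinSequence, ss: SecondaryStructureString | None = None) -> np.ndarray:
    """Six structure features: H/E/C fractions and longest H/E/C run / L."""
    if ss is None:
        ss = predict_ss_fallback(seq)
    if len(ss.states) != len(seq.residues):
        raise ValueError(
            f"{seq.id!r}: secondary-structure length {len(ss.states)} "
            f"!= sequence length {len(seq.residues)}"
        )
    L = len(ss.states)
    out = np.zeros(6)
    for k, state in enumerate("HEC"):
        out[k] = ss.states.count(state) / L
        longest = run = 0
        for c in ss.states:
            run = run + 1 if c == state else 0
            longest = max(longest, run)
        out[3 + k] = longest / L
    return out


# -- sequence order ----------------------------------------------------------

def _coupling_numbers(idx: np.ndarray, maxlag: int) -> np.ndarray:
    """tau_d = sum_i dist(R_i, R_{i+d})^2 for d = 1..maxlag."""
    d2 = _DIST**2
    return np.array([d2[idx[:-d], idx[d:]].sum() for d in range(1, maxlag + 1)])


def _check_socn_length(seq: ProteinSequence, maxlag: int) -> np.ndarray:
    idx = _encode(seq)
    if len(idx) <= maxlag:
        raise ShortSequenceError(
            f"{seq.id!r}: sequence-order descriptors with maxlag={maxlag} "
            f"need L > {maxlag} (minimum length {maxlag + 1}), got L={len(idx)}"
        )
    return idx


def extract_socn(seq: ProteinSequence, params: DescriptorParams = DescriptorParams()) -> np.ndarray:
    """Sequence-order coupling numbers tau_1..tau_maxlag."""
    idx = _check_socn_length(seq, params.maxlag_so)
    return _coupling_numbers(idx, params.maxlag_so)


def extract_qso(seq: ProteinSequence, params: DescriptorParams = DescriptorParams()) -> np.ndarray:
    """Quasi-sequence-order: 20 composition + 20 coupling terms, sum 1."""
    idx = _check_socn_length(seq, params.maxlag_so)
    freqs = np.bincount(idx, minlength=20) / len(idx)
    taus = _coupling_numbers(idx, params.maxlag_so)
    denom = freqs.sum() + params.w_qso * taus.sum()
    return np.concatenate([freqs / denom, params.w_qso * taus / denom])


# -- PSSM transitions --------------------------------------------------------

def _pseudo_profile(idx: np.ndarray) -> np.ndarray:
    """BLOSUM62-row pseudo-profile for sequences without a real PSSM."""
    global _BLOSUM
    if _BLOSUM is None:
        _BLOSUM = blosum62_rows()
    return _BLOSUM[idx]


def extract_pssm_transition(seq: ProteinSequence, profile: PSSMProfile | None = None) -> np.ndarray:
    """PSSM transition scores between adjacent positions (400 features).

    Scores are squashed with the logistic sigma(x) = 1/(1+exp(-x)); feature
    (a, b) is the mean over adjacent position pairs of
    sigma(S[i, a]) * sigma(S[i+1, b]).  Without a profile, a BLOSUM62
    pseudo-profile keeps the family computable from sequence alone.
    """
    idx = _encode(seq)
    L = len(idx)
    if L < 2:
        raise ShortSequenceError(f"{seq.id!r}: PSSM transitions need L >= 2")
    if profile is None:
        scores = _pseudo_profile(idx)
    else:
        scores = profile.scores
        if scores.shape[0] != L:
            raise ValueError(
                f"{seq.id!r}: PSSM has {scores.shape[0]} rows for sequence length {L}"
            )
    sig = 1.0 / (1.0 + np.exp(-scores))
    return (sig[:-1].T @ sig[1:]).ravel() / (L - 1)


# -- full featurization ------------------------------------------------------

_FAMILY_DIMS = (20, 400, 30, 40, 147, 6, 20, 40, 400)


def featurize(
    seqs: Sequence[ProteinSequence],
    profiles: Mapping[str, PSSMProfile] | None = None,
    ss: Mapping[str, SecondaryStructureString] | None = None,
    params: DescriptorParams = DescriptorParams(),
    labels: Sequence[int] | np.ndarray | None = None,
) -> FeatureMatrix:
    """Compute the full 1,103-feature vector for each sequence.

    ``profiles`` and ``ss`` map sequence ids to externally computed PSSM /
    secondary-structure inputs; sequences without an entry fall back to the
    internal pseudo-profile and propensity predictor (recorded in
    ``metadata``).  Sequences must satisfy the strictest lag precondition,
    L > maxlag_so (= 20 by default).
    """
    profiles = profiles or {}
    ss = ss or {}
    rows = []
    fallback_pssm: list[str] = []
    fallback_ss: list[str] = []
    for s in seqs:
        prof = profiles.get(s.id)
        if prof is None:
            fallback_pssm.append(s.id)
        sstruct = ss.get(s.id)
        if sstruct is None:
            fallback_ss.append(s.id)
        try:
            parts = (
                extract_aac(s),
                extract_dc(s),
                extract_paac(s, params),
                extract_apaac(s, params),
                extract_ctd(s),
                extract_ss(s, sstruct),
                extract_socn(s, params),
                extract_qso(s, params),
                extract_pssm_transition(s, prof),
            )
        except ValueError as exc:
            raise type(exc)(f"featurize failed for {s.id!r}: {exc}") from exc
        for part, dim in zip(parts, _FAMILY_DIMS):
            assert len(part) == dim, f"family dim {len(part)} != {dim}"
        row = np.concatenate(parts)
        assert row.shape == (1103,)
        rows.append(row)
    return FeatureMatrix(
        ids=tuple(s.id for s in seqs),
        values=np.vstack(rows) if rows else np.empty((0, 1103)),
        schema=FeatureSchema.full(),
        labels=None if labels is None else np.asarray(labels),
        metadata={
            "schema_version": SCHEMA_VERSION,
            "params": {
                "lambda_paac": params.lambda_paac,
                "lambda_apaac": params.lambda_apaac,
                "w_paac": params.w_paac,
                "w_apaac": params.w_apaac,
                "maxlag_so": params.maxlag_so,
                "w_qso": params.w_qso,
            },
            "pssm_fallback_ids": fallback_pssm,
            "ss_fallback_ids": fallback_ss,
        },
    )
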
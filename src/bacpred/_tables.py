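"""Physicochemical property tables used by the descriptor families.

Scales are stored in the canonical ``ARNDCQEGHILKMFPSTWYV`` order
(:mod:`bacpred._alphabet`).  Three per-residue scales (hydrophobicity,
hydrophilicity, side-chain mass) drive the pseudo amino-acid composition
correlation terms and, in standardized form, the physicochemical distance
matrix behind the sequence-order descriptors.  The composition/transition/
distribution (CTD) model uses seven properties, each partitioning the 20
amino acids into three disjoint, exhaustive groups.
"""

from __future__ import annotations

import numpy as np

from ._alphabet import ALPHABET, AA_INDEX

# ---------------------------------------------------------------------------
# Per-residue scales (order: A R N D C Q E G H I L K M F P S T W Y V)
# ---------------------------------------------------------------------------

#: Hydrophobicity (Tanford-style scale conventional for pseudo-AAC).
HYDROPHOBICITY = np.array([
    0.62, -2.53, -0.78, -0.90, 0.29, -0.85, -0.74, 0.48, -0.40, 1.38,
    1.06, -1.50, 0.64, 1.19, 0.12, -0.18, -0.05, 0.81, 0.26, 1.08,
])

#: Hydrophilicity (Hopp-Woods).
HYDROPHILICITY = np.array([
    -0.5, 3.0, 0.2, 3.0, -1.0, 0.2, 3.0, 0.0, -0.5, -1.8,
    -1.8, 3.0, -1.3, -2.5, 0.0, 0.3, -0.4, -3.4, -2.3, -1.5,
])

#: Side-chain mass (Da).
SIDE_CHAIN_MASS = np.array([
    15.0, 101.0, 58.0, 59.0, 47.0, 72.0, 73.0, 1.0, 82.0, 57.0,
    57.0, 73.0, 75.0, 91.0, 42.0, 31.0, 45.0, 130.0, 107.0, 43.0,
])


def standardize(scale: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance version of a 20-residue scale.

    Population standard deviation (denominator 20), the convention used in
    pseudo amino-acid composition.
    """
    return (scale - scale.mean()) / scale.std()


#: 3 x 20 matrix of the standardized PseAAC scales, row order
#: (hydrophobicity, hydrophilicity, side-chain mass).
PAAC_SCALES = np.vstack([
    standardize(HYDROPHOBICITY),
    standardize(HYDROPHILICITY),
    standardize(SIDE_CHAIN_MASS),
])


def physicochemical_distance_matrix() -> np.ndarray:
    """20 x 20 amino-acid distance matrix for the sequence-order descriptors.

    Root-mean-square distance in the three-dimensional standardized property
    space (hydrophobicity, hydrophilicity, side-chain mass)::

        D(a, b) = sqrt( mean_k (P'_k(a) - P'_k(b))^2 )

    Symmetric with zero diagonal, so homopolymers have zero coupling numbers.
    """
    diff = PAAC_SCALES[:, :, None] - PAAC_SCALES[:, None, :]
    return np.sqrt(np.mean(diff**2, axis=0))


# ---------------------------------------------------------------------------
# CTD: seven properties x three groups (Dubchak convention)
# ---------------------------------------------------------------------------

#: Ordered (property name, (group1, group2, group3)) pairs.  The property
#: order fixes feature naming: distribution features are property-major, so
#: e.g. the solvent-accessibility (7th property) group-1 block starts at
#: dist_91 and its 50% quantile is dist_93.  Group 1 of solvent accessibility
#: is the buried-residue group.
CTD_PROPERTIES: tuple[tuple[str, tuple[str, str, str]], ...] = (
    ("hydrophobicity",        ("RKEDQN",   "GASTPHY",  "CLVIMFW")),
    ("normalized_vdw_volume", ("GASCTPD",  "NVEQIL",   "MHKFRYW")),
    ("polarity",              ("LIFWCMVY", "PATGS",    "HQRKNED")),
    ("polarizability",        ("GASDT",    "CPNVEQIL", "KMHFRYW")),
    ("charge",                ("KR",       "ANCQGHILMFPSTWYV", "DE")),
    ("secondary_structure",   ("EALMQKRH", "VIYCWFT",  "GNPSD")),
    ("solvent_accessibility", ("ALFCGIVW", "RKQEND",   "MSPTHY")),
)


def _group_lookup() -> np.ndarray:
    """7 x 20 int array: group id (0/1/2) of each residue per property."""
    table = np.full((len(CTD_PROPERTIES), 20), -1, dtype=np.int64)
    for p, (_, groups) in enumerate(CTD_PROPERTIES):
        for g, members in enumerate(groups):
            for aa in members:
                table[p, AA_INDEX[aa]] = g
    if (table < 0).any():
        raise AssertionError("CTD groups do not cover the alphabet")
    return table


CTD_GROUP_OF = _group_lookup()


# ---------------------------------------------------------------------------
# Chou-Fasman-style secondary-structure propensities (H / E / C)
# ---------------------------------------------------------------------------

#: 3 x 20 propensity matrix, rows (helix, strand, coil).  Used only by the
#: internal fallback predictor when no external .ss2 profile is supplied.
SS_PROPENSITY = np.array([
    # A     R     N     D     C     Q     E     G     H     I
    # L     K     M     F     P     S     T     W     Y     V
    [1.42, 0.98, 0.67, 1.01, 0.70, 1.11, 1.51, 0.57, 1.00, 1.08,
     1.21, 1.16, 1.45, 1.13, 0.57, 0.77, 0.83, 1.08, 0.69, 1.06],
    [0.83, 0.93, 0.89, 0.54, 1.19, 1.10, 0.37, 0.75, 0.87, 1.60,
     1.30, 0.74, 1.05, 1.38, 0.55, 0.75, 1.19, 1.37, 1.47, 1.70],
    [0.66, 0.95, 1.56, 1.46, 1.19, 0.98, 0.74, 1.56, 0.95, 0.47,
     0.59, 1.01, 0.60, 0.60, 1.52, 1.43, 0.96, 0.96, 1.14, 0.50],
])


def blosum62_rows() -> np.ndarray:
    """BLOSUM62 scores as a 20 x 20 matrix in canonical alphabet order.

    Used to build a pseudo-profile when no PSSM is available: row i of the
    pseudo-profile for a sequence is the BLOSUM62 row of residue i.
    """
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    out = np.empty((20, 20))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = mat[a, b]
    return out
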
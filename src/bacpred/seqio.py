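"""Readers and writers for the formats the toolkit touches.

FASTA protein sequences (via Biopython), PSI-BLAST ASCII PSSM profiles,
PSIPRED ``.ss2`` secondary-structure predictions, and the tab-separated
feature-table artifact used between pipeline stages.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._alphabet import ALPHABET
from .schema import SCHEMA_VERSION, FeatureMatrix, FeatureSchema

logger = logging.getLogger(__name__)

_VALID_RESIDUES = frozenset(ALPHABET)
_SS_STATES = frozenset("HEC")


class SequenceError(ValueError):
    """Malformed or invalid sequence input."""


class ProfileError(ValueError):
    """Malformed PSSM or secondary-structure profile."""


class FeatureTableError(ValueError):
    """Malformed feature-table artifact."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence over the 20 standard amino acids."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in _VALID_RESIDUES:
                raise SequenceError(
                    f"sequence {self.id!r}: invalid residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PSSMProfile:
    """Per-position log-odds scores, columns in canonical alphabet order."""

    sequence_id: str
    scores: np.ndarray  # L x 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=np.float64))
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ProfileError(
                f"PSSM for {self.sequence_id!r} must be L x 20, "
                f"got shape {self.scores.shape}"
            )


@dataclass(frozen=True)
class SecondaryStructureString:
    """Per-residue three-state secondary structure (H=helix, E=strand, C=coil)."""

    sequence_id: str
    states: str

    def __post_init__(self) -> None:
        bad = set(self.states) - _SS_STATES
        if bad:
            raise ProfileError(
                f"secondary structure for {self.sequence_id!r}: "
                f"unknown state(s) {sorted(bad)}"
            )


def read_fasta(path: str | Path, skip_invalid: bool = False) -> list[ProteinSequence]:
    """Read a multi-record protein FASTA.

    Records containing residues outside the 20-letter alphabet are rejected
    with :class:`SequenceError` by default; with ``skip_invalid=True`` they
    are dropped with a logged warning instead.  Duplicate record ids are
    always an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            out.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper()))
        except SequenceError:
            if skip_invalid:
                logger.warning("dropping record %r: non-standard residues", rec.id)
                continue
            raise
    if not out:
        raise SequenceError(f"all records in {path} were dropped as invalid")
    return out


def write_fasta(seqs: list[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


# -- PSI-BLAST ASCII PSSM ----------------------------------------------------

_PSSM_ROW = re.compile(r"^\s*(\d+)\s+([A-Z])\s+(.*)$")


def read_pssm(path: str | Path, sequence_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` profile.

    Only the first 20 (log-odds) score columns are consumed.  Columns are
    re-ordered from the file's declared header order into the canonical
    alphabet order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_order: list[str] | None = None
    header_line = 0
    for i, line in enumerate(lines):
        cols = line.split()
        if len(cols) >= 20 and all(c in _VALID_RESIDUES and len(c) == 1 for c in cols[:20]):
            header_order = cols[:20]
            header_line = i
            break
    if header_order is None:
        raise ProfileError(f"{path}: no PSSM column header found")
    if len(set(header_order)) != 20:
        raise ProfileError(f"{path}: PSSM header does not list 20 distinct residues")

    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[header_line + 1:], start=header_line + 2):
        if not line.strip():
            continue
        m = _PSSM_ROW.match(line)
        if m is None:
            break  # footer statistics
        fields = m.group(3).split()
        if len(fields) < 20:
            raise ProfileError(
                f"{path}, line {lineno}: expected >= 20 score columns, got {len(fields)}"
            )
        try:
            rows.append([float(x) for x in fields[:20]])
        except ValueError as exc:
            raise ProfileError(f"{path}, line {lineno}: {exc}") from None
    if not rows:
        raise ProfileError(f"{path}: no score rows found")

    scores = np.asarray(rows)
    # permute file columns into canonical order
    perm = [header_order.index(aa) for aa in ALPHABET]
    return PSSMProfile(sequence_id=sequence_id or path.stem, scores=scores[:, perm])


# -- PSIPRED .ss2 ------------------------------------------------------------

def read_ss2(path: str | Path, sequence_id: str | None = None) -> SecondaryStructureString:
    """Parse a PSIPRED ``.ss2`` file into an H/E/C state string.

    PSIPRED's coil symbol ``C`` maps to C directly; lines are
    ``pos residue state conf_C conf_H conf_E``.
    """
    path = Path(path)
    states: list[str] = []
    expected_pos = 1
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < 3:
            raise ProfileError(f"{path}, line {lineno}: expected >= 3 fields")
        try:
            pos = int(fields[0])
        except ValueError:
            raise ProfileError(f"{path}, line {lineno}: bad position {fields[0]!r}") from None
        if pos != expected_pos:
            raise ProfileError(
                f"{path}, line {lineno}: position gap (expected {expected_pos}, got {pos})"
            )
        expected_pos += 1
        state = fields[2]
        if state not in _SS_STATES:
            raise ProfileError(f"{path}, line {lineno}: unknown state {state!r}")
        states.append(state)
    if not states:
        raise ProfileError(f"{path}: empty secondary-structure profile")
    return SecondaryStructureString(sequence_id=sequence_id or path.stem, states="".join(states))


# -- TSV feature-table artifact ----------------------------------------------

_ID_COL = "sample_id"
_LABEL_COL = "label"


def write_feature_table(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write the TSV artifact: sample_id, features..., [label].

    Floats are written at 10 significant digits so a read/write round trip is
    bit-stable.
    """
    df = pd.DataFrame(matrix.values, columns=list(matrix.schema.names))
    df.insert(0, _ID_COL, list(matrix.ids))
    if matrix.labels is not None:
        df[_LABEL_COL] = matrix.labels
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_table(path: str | Path, require_labels: bool = False) -> FeatureMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        raise FeatureTableError(f"{path}: duplicated feature name in header")
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != _ID_COL:
        raise FeatureTableError(f"{path}: first column must be {_ID_COL!r}")
    has_labels = df.columns[-1] == _LABEL_COL
    if require_labels and not has_labels:
        raise FeatureTableError(f"{path}: label column required but absent")
    feature_cols = list(df.columns[1:-1] if has_labels else df.columns[1:])
    if len(set(feature_cols)) != len(feature_cols):
        raise FeatureTableError(f"{path}: duplicated feature name in header")
    try:
        schema = FeatureSchema(tuple(feature_cols))
    except (ValueError, KeyError) as exc:
        raise FeatureTableError(f"{path}: {exc}") from None
    return FeatureMatrix(
        ids=tuple(str(i) for i in df[_ID_COL]),
        values=df[feature_cols].to_numpy(dtype=np.float64),
        schema=schema,
        labels=df[_LABEL_COL].to_numpy() if has_labels else None,
        metadata={"schema_version": SCHEMA_VERSION, "source": str(path)},
    )
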
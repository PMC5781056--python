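"""Readers and writers for the four external input formats.

The pipeline consumes (a) protein sequences in FASTA, (b) per-protein
evolutionary profiles in the PSI-BLAST ASCII PSSM dialect, (c) per-protein
structural profiles in an SPD3-style whitespace table (accessible surface
area, three secondary-structure probabilities and four backbone angles), and
(d) a site-annotation table mapping (protein id, 1-based position) to a
succinylated/non-succinylated label.  It emits a flat per-lysine feature
table as TSV.

All coordinates in external files are 1-based and inclusive.  Amino-acid
columns of every PSSM are re-mapped at parse time to the canonical PSI-BLAST
header order ``A R N D C Q E G H I L K M F P S T W Y V`` so that downstream
feature layouts are independent of the file's own column order.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical amino-acid column order (PSI-BLAST header order).
AA_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Residue letters accepted in sequences: 20 standard plus ambiguity codes.
SEQUENCE_ALPHABET = frozenset(AA_ORDER) | frozenset("XBZU")

#: Number of feature columns in the assembled per-lysine descriptor.
N_FEATURES = 657


class FormatError(ValueError):
    """A file does not conform to its expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass
class ProteinRecord:
    """A protein sequence with (optional) annotated lysine sites.

    ``sites`` holds ``(position, label)`` pairs with 1-based positions and
    labels in {+1 succinylated, -1 non-succinylated}.
    """

    id: str
    sequence: str
    sites: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal sequence characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def lysine_positions(self) -> list[int]:
        """1-based positions of every K residue."""
        return [i + 1 for i, aa in enumerate(self.sequence) if aa == "K"]


@dataclass
class PSSMatrix:
    """L x 20 evolutionary profile on a linear-probability scale.

    Rows follow the protein sequence; columns follow :data:`AA_ORDER`.
    Every entry lies in [0, 1].
    """

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValidationError(
                f"PSSM for {self.protein_id!r}: expected L x 20, "
                f"got {self.values.shape}"
            )
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValidationError(
                f"PSSM for {self.protein_id!r}: entries outside [0, 1]"
            )

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class StructuralProfile:
    """Per-residue structural tracks predicted from sequence.

    ``asa`` is solvent-accessible surface area in square Angstroms,
    ``ss_probs`` the L x 3 matrix of (helix, strand, coil) probabilities in
    that fixed (ph, pe, pc) order, and ``angles`` the L x 4 matrix of the
    backbone angles (phi, psi, theta, tau) in degrees.
    """

    protein_id: str
    asa: np.ndarray
    ss_probs: np.ndarray
    angles: np.ndarray
    ss_sum_tolerance: float = 0.05

    def __post_init__(self) -> None:
        self.asa = np.asarray(self.asa, dtype=float).ravel()
        self.ss_probs = np.asarray(self.ss_probs, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        L = self.asa.shape[0]
        if self.ss_probs.shape != (L, 3) or self.angles.shape != (L, 4):
            raise ValidationError(
                f"profile for {self.protein_id!r}: inconsistent track shapes"
            )
        if np.any(self.asa < 0):
            raise ValidationError(
                f"profile for {self.protein_id!r}: negative ASA value"
            )
        if np.any(self.angles < -180.0) or np.any(self.angles > 180.0):
            raise ValidationError(
                f"profile for {self.protein_id!r}: angle outside [-180, 180]"
            )
        sums = self.ss_probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > self.ss_sum_tolerance):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValidationError(
                f"profile for {self.protein_id!r}: secondary-structure "
                f"probabilities at row {bad + 1} sum to {sums[bad]:.3f}"
            )

    def __len__(self) -> int:
        return self.asa.shape[0]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects (no sites).

    The record id is the first whitespace-delimited token of the header and
    sequences are uppercased.  Raises :class:`FormatError` on an empty file
    and :class:`ValidationError` on illegal sequence characters.
    """
    with open(path) as fh:
        records = [
            ProteinRecord(id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(fh, "fasta")
        ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

_INT_RE = re.compile(r"^-?\d+$")
_NUM_RE = re.compile(r"^-?\d+(\.\d+)?$")


def _is_aa_header(tokens: list[str]) -> bool:
    return len(tokens) == 40 and all(t in _AA_INDEX for t in tokens)


def read_pssm(path, scale_mode: str = "percent", protein_id: str | None = None) -> PSSMatrix:
    """Parse a PSI-BLAST ASCII PSSM into linear probabilities.

    Each data row carries the position, the residue, 20 log-odds scores and
    20 weighted observed percentages (plus two optional trailing statistics).
    ``scale_mode`` selects the probability scale:

    ``"percent"`` (default)
        weighted observed percentages divided by 100 — the only columns
        already on a linear-probability scale.
    ``"logodds-logistic"``
        logistic transform ``1 / (1 + exp(-s))`` of the log-odds scores.

    Columns are re-mapped to :data:`AA_ORDER` using the file's own header.
    """
    if scale_mode not in ("percent", "logodds-logistic"):
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    if protein_id is None:
        protein_id = _stem(path)

    logodds_order: list[str] | None = None
    percent_order: list[str] | None = None
    logodds_rows: list[list[float]] = []
    percent_rows: list[list[float]] = []
    n_data_lines = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if logodds_order is None and _is_aa_header(tokens):
                logodds_order = tokens[:20]
                percent_order = tokens[20:]
                continue
            if _INT_RE.match(tokens[0]) and len(tokens) >= 3:
                numeric_tail = tokens[2:]
                n_numeric = sum(1 for t in numeric_tail if _NUM_RE.match(t))
                if n_numeric != len(numeric_tail) or not 40 <= n_numeric <= 42:
                    raise FormatError(
                        f"{path}:{lineno}: expected 40 numeric score columns "
                        f"(plus up to 2 statistics), found {n_numeric}"
                    )
                logodds_rows.append([float(t) for t in numeric_tail[:20]])
                percent_rows.append([float(t) for t in numeric_tail[20:40]])
                n_data_lines += 1

    if not logodds_rows:
        raise FormatError(f"{path}: no PSSM data rows found")
    if logodds_order is None:
        # no header line: assume canonical order
        logodds_order = list(AA_ORDER)
        percent_order = list(AA_ORDER)

    if scale_mode == "percent":
        raw = np.asarray(percent_rows, dtype=float)
        order = percent_order
        values = raw / 100.0
    else:
        raw = np.asarray(logodds_rows, dtype=float)
        order = logodds_order
        values = 1.0 / (1.0 + np.exp(-raw))

    # re-map columns to the canonical order
    perm = [order.index(a) for a in AA_ORDER]
    values = values[:, perm]
    if values.shape[0] != n_data_lines:
        raise FormatError(f"{path}: row count mismatch after parsing")
    return PSSMatrix(protein_id=protein_id, values=values)


def write_pssm(matrix: PSSMatrix, path) -> None:
    """Write a :class:`PSSMatrix` in the PSI-BLAST ASCII dialect.

    The percentage columns carry ``100 * p``; values that are not integral
    are written with decimals so that a parse -> write -> parse round trip
    reproduces the matrix exactly.  Log-odds columns are derived as
    ``round(10 * log2(p / 0.05))`` with probabilities floored at 1e-4, which
    mimics realistic score magnitudes but is informational only.
    """
    p = matrix.values
    with np.errstate(divide="ignore"):
        logodds = np.round(10.0 * np.log2(np.maximum(p, 1e-4) / 0.05)).astype(int)
    header = "  ".join(AA_ORDER)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        fh.write("          " + header + "   " + header + "\n")
        for i in range(p.shape[0]):
            percents = []
            for v in 100.0 * p[i]:
                r = round(v)
                percents.append(str(int(r)) if abs(v - r) < 1e-9 else f"{v:.6f}")
            fh.write(
                f"{i + 1:5d} X  "
                + " ".join(f"{s:>3d}" for s in logodds[i])
                + "  "
                + " ".join(f"{s:>3s}" for s in percents)
                + "  0.00 0.00\n"
            )
        fh.write("\n")


# ---------------------------------------------------------------------------
# SPD3-style structural profile
# ---------------------------------------------------------------------------

#: Default 0-based column mapping of the SPD3 dialect.
SPD3_COLUMNS = {
    "index": 0,
    "residue": 1,
    "ss": 2,
    "asa": 3,
    "phi": 4,
    "psi": 5,
    "theta": 6,
    "tau": 7,
    "pc": 8,
    "pe": 9,
    "ph": 10,
}


def read_structural_profile(
    path, columns: dict[str, int] | None = None, protein_id: str | None = None
) -> StructuralProfile:
    """Parse an SPD3-style table into a :class:`StructuralProfile`.

    ``columns`` maps field names to 0-based column indices (defaults to
    :data:`SPD3_COLUMNS`).  The returned ``ss_probs`` columns are always in
    (ph, pe, pc) order regardless of the file's column layout.
    """
    cols = dict(SPD3_COLUMNS)
    if columns:
        cols.update(columns)
    missing = {k for k in ("asa", "phi", "psi", "theta", "tau", "pc", "pe", "ph")} - set(cols)
    if missing:
        raise FormatError(f"{path}: column mapping lacks {sorted(missing)}")
    if protein_id is None:
        protein_id = _stem(path)

    needed = max(cols.values()) + 1
    asa, angles, ss = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < needed:
                raise FormatError(
                    f"{path}:{lineno}: expected at least {needed} columns, "
                    f"found {len(tokens)}"
                )
            try:
                asa.append(float(tokens[cols["asa"]]))
                angles.append(
                    [float(tokens[cols[a]]) for a in ("phi", "psi", "theta", "tau")]
                )
                ss.append(
                    [float(tokens[cols[a]]) for a in ("ph", "pe", "pc")]
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not asa:
        raise FormatError(f"{path}: no data rows found")
    return StructuralProfile(
        protein_id=protein_id,
        asa=np.asarray(asa),
        ss_probs=np.asarray(ss),
        angles=np.asarray(angles),
    )


def write_structural_profile(profile: StructuralProfile, path) -> None:
    """Write a profile in the SPD3-style dialect read by
    :func:`read_structural_profile`."""
    with open(path, "w") as fh:
        fh.write("# index AA SS ASA Phi Psi Theta(i-1=>i+1) Tau(i-2=>i+2) P(C) P(E) P(H)\n")
        for i in range(len(profile)):
            ph, pe, pc = profile.ss_probs[i]
            phi, psi, theta, tau = profile.angles[i]
            fh.write(
                f"{i + 1} X C {profile.asa[i]:.4f} {phi:.4f} {psi:.4f} "
                f"{theta:.4f} {tau:.4f} {pc:.6f} {pe:.6f} {ph:.6f}\n"
            )


# ---------------------------------------------------------------------------
# Site annotations
# ---------------------------------------------------------------------------

_POSITIVE_TOKENS = {"+1", "1", "pos", "positive", "succinylated"}
_NEGATIVE_TOKENS = {"-1", "neg", "negative", "non-succinylated"}


def read_sites(path) -> dict[str, list[tuple[int, int]]]:
    """Read the site-annotation TSV (protein_id, position, label).

    Labels are normalised to {+1, -1}.  Duplicate (id, position) rows and
    non-positive positions are errors.  A single optional header row is
    tolerated.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            tokens = [t.strip() for t in tokens]
            if len(tokens) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            pid, pos_token, label_token = tokens[0], tokens[1], tokens[2].lower()
            if lineno == 1 and not _INT_RE.match(pos_token):
                continue  # header row
            try:
                pos = int(pos_token)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer position {pos_token!r}") from None
            if pos < 1:
                raise ValidationError(f"{path}:{lineno}: non-positive position {pos}")
            if label_token in _POSITIVE_TOKENS:
                label = 1
            elif label_token in _NEGATIVE_TOKENS:
                label = -1
            else:
                raise ValidationError(f"{path}:{lineno}: unknown label {tokens[2]!r}")
            key = (pid, pos)
            if key in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate site {key}")
            seen.add(key)
            out.setdefault(pid, []).append((pos, label))
    return out


def write_sites(sites: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for pid in sites:
            for pos, label in sites[pid]:
                fh.write(f"{pid}\t{pos}\t{label:+d}\n")


def attach_sites(
    records: list[ProteinRecord], sites: dict[str, list[tuple[int, int]]]
) -> list[ProteinRecord]:
    """Attach annotated sites to protein records, validating coordinates.

    Positions beyond the sequence are errors; annotated positions whose
    residue is not lysine are skipped with a warning (sequence-version drift
    in annotations is tolerated rather than fatal).
    """
    by_id = {rec.id: rec for rec in records}
    unknown = set(sites) - set(by_id)
    if unknown:
        raise ValidationError(f"sites reference unknown proteins: {sorted(unknown)}")
    for pid, site_list in sites.items():
        rec = by_id[pid]
        kept = []
        for pos, label in site_list:
            if pos > len(rec):
                raise ValidationError(
                    f"protein {pid!r}: site position {pos} exceeds length {len(rec)}"
                )
            if rec.sequence[pos - 1] != "K":
                warnings.warn(
                    f"protein {pid!r}: annotated position {pos} is "
                    f"{rec.sequence[pos - 1]!r}, not lysine; skipping",
                    stacklevel=2,
                )
                continue
            kept.append((pos, label))
        rec.sites = kept
    return records


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

def feature_columns(n_features: int = N_FEATURES) -> list[str]:
    return [f"f{i + 1:04d}" for i in range(n_features)]


def write_feature_table(path, ids, positions, labels, X) -> None:
    """Write the per-lysine feature table as TSV.

    One row per lysine: protein_id, position, label, then the feature
    columns ``f0001..``.
    """
    X = np.asarray(X, dtype=float)
    df = pd.DataFrame(X, columns=feature_columns(X.shape[1]))
    df.insert(0, "protein_id", list(ids))
    df.insert(1, "position", list(positions))
    df.insert(2, "label", list(labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "position", "label"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: feature table lacks columns {sorted(required - set(df.columns))}")
    return df


def _stem(path) -> str:
    import os

    name = os.path.basename(str(path))
    return name.rsplit(".", 1)[0] if "." in name else name
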
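"""Per-lysine feature vectors: structural tracks plus bigram profiles.

A window's evolutionary profile (W x 20) and secondary-structure profile
(W x 3) are each condensed into a bigram profile

    B[p, q] = sum_{k=1}^{W-1} m[k, p] * m[k+1, q]

which counts soft transitions between consecutive residues and — crucially —
has a dimensionality (K x K) independent of the window size.  The assembled
descriptor concatenates the eight raw structural tracks over the window
(8 x 31 = 248 values by default), the flattened 20 x 20 PSSM bigram
(400 values) and the flattened 3 x 3 secondary-structure bigram (9 values):
657 components in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .balance import LabeledDataset
from .io_formats import PSSMatrix, ProteinRecord, StructuralProfile
from .windows import DEFAULT_FLANK, extract_window_tracks, window_indices

#: Block sizes of the default descriptor.
N_STRUCT = 248
N_PSSM_BIGRAM = 400
N_SS_BIGRAM = 9
N_TOTAL = N_STRUCT + N_PSSM_BIGRAM + N_SS_BIGRAM  # 657


class FeatureError(ValueError):
    pass


@dataclass
class BigramProfile:
    """K x K bigram occurrence matrix and its row-major flattening."""

    matrix: np.ndarray

    @property
    def flattened(self) -> np.ndarray:
        """Row-major flatten (first index slowest): B11, B12, ..., BKK."""
        return self.matrix.ravel()


def bigram(track: np.ndarray) -> BigramProfile:
    """Bigram profile of a window track (rows = residues, columns = states).

    ``B[p, q] = sum_k track[k, p] * track[k+1, q]`` over the W-1 consecutive
    row pairs.  Works for any number of columns K >= 1 (20 for PSSM, 3 for
    secondary structure).
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[0] < 2:
        raise FeatureError(
            f"bigram needs a 2-D track with >= 2 rows, got shape {track.shape}"
        )
    B = track[:-1].T @ track[1:]
    return BigramProfile(matrix=B)


def structural_block(window_struct: np.ndarray) -> np.ndarray:
    """Concatenate structural tracks track-major over the window.

    For a W x 8 input the output is length 8*W: all W ASA values (slot
    -flank..+flank), then all W helix probabilities, and so on through tau.
    """
    window_struct = np.asarray(window_struct, dtype=float)
    if window_struct.ndim != 2 or window_struct.shape[1] != 8:
        raise FeatureError(
            f"expected a W x 8 structural window, got shape {window_struct.shape}"
        )
    return window_struct.T.ravel()


@dataclass
class LysineFeatureVector:
    """The assembled per-lysine descriptor with provenance."""

    protein_id: str
    position: int
    values: np.ndarray
    label: int = 0  # +1 succinylated, -1 non-succinylated, 0 unlabeled


def assemble(
    window_struct: np.ndarray,
    window_pssm: np.ndarray,
    window_ss: np.ndarray,
    use_bigram: bool = True,
) -> np.ndarray:
    """Assemble the flat feature vector from the three window tracks.

    With ``use_bigram`` (default) the layout is
    ``structural(8W) | PSSM-bigram(400) | SS-bigram(9)`` — 657 components at
    the default window of 31.  With ``use_bigram=False`` the raw window
    profiles are flattened instead (ablation configuration):
    ``structural(8W) | PSSM rows(20W) | SS rows(3W)``.
    """
    window_struct = np.asarray(window_struct, dtype=float)
    window_pssm = np.asarray(window_pssm, dtype=float)
    window_ss = np.asarray(window_ss, dtype=float)
    W = window_struct.shape[0]
    if window_pssm.shape != (W, 20) or window_ss.shape != (W, 3):
        raise FeatureError(
            f"inconsistent window shapes: struct {window_struct.shape}, "
            f"pssm {window_pssm.shape}, ss {window_ss.shape}"
        )
    blocks = [structural_block(window_struct)]
    if use_bigram:
        blocks.append(bigram(window_pssm).flattened)
        blocks.append(bigram(window_ss).flattened)
    else:
        blocks.append(window_pssm.ravel())
        blocks.append(window_ss.ravel())
    return np.concatenate(blocks)


def featurize_protein(
    record: ProteinRecord,
    pssm: PSSMatrix,
    profile: StructuralProfile,
    flank: int = DEFAULT_FLANK,
    padding: str = "mirror-terminus",
    use_bigram: bool = True,
    prediction_mode: bool = False,
) -> list[LysineFeatureVector]:
    """Feature vectors for a protein's lysines.

    In the default (training) mode one vector is produced per annotated
    site, carrying its label.  In ``prediction_mode`` every lysine in the
    sequence yields an unlabeled vector instead.
    """
    L = len(record)
    if len(pssm) != L or len(profile) != L:
        raise FeatureError(
            f"protein {record.id!r}: sequence length {L} does not match "
            f"pssm ({len(pssm)}) / profile ({len(profile)})"
        )
    if prediction_mode:
        targets = [(pos, 0) for pos in record.lysine_positions()]
    else:
        targets = record.sites
    out = []
    for pos, label in targets:
        win = window_indices(L, pos, flank=flank, padding=padding, protein_id=record.id)
        wp, ws, wstruct = extract_window_tracks(win, pssm, profile)
        out.append(
            LysineFeatureVector(
                protein_id=record.id,
                position=pos,
                values=assemble(wstruct, wp, ws, use_bigram=use_bigram),
                label=label,
            )
        )
    return out


def build_dataset(
    records: list[ProteinRecord],
    pssms: dict[str, PSSMatrix],
    profiles: dict[str, StructuralProfile],
    flank: int = DEFAULT_FLANK,
    padding: str = "mirror-terminus",
    use_bigram: bool = True,
    prediction_mode: bool = False,
) -> LabeledDataset:
    """Featurize all proteins into a single labeled dataset.

    Sample ids are ``"<protein_id>:<position>"``.
    """
    vectors: list[LysineFeatureVector] = []
    for rec in records:
        if rec.id not in pssms:
            raise FeatureError(f"missing PSSM for protein {rec.id!r}")
        if rec.id not in profiles:
            raise FeatureError(f"missing structural profile for protein {rec.id!r}")
        vectors.extend(
            featurize_protein(
                rec,
                pssms[rec.id],
                profiles[rec.id],
                flank=flank,
                padding=padding,
                use_bigram=use_bigram,
                prediction_mode=prediction_mode,
            )
        )
    if not vectors:
        return LabeledDataset(
            X=np.empty((0, N_TOTAL)), y=np.empty(0, dtype=int), ids=[]
        )
    X = np.vstack([v.values for v in vectors])
    y = np.array([v.label for v in vectors], dtype=int)
    ids = [f"{v.protein_id}:{v.position}" for v in vectors]
    return LabeledDataset(X=X, y=y, ids=ids)
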
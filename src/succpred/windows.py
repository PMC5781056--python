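"""Peptide windows around lysine residues with mirror padding.

Each candidate lysine is described by the 31-residue peptide consisting of
the 15 residues upstream, the lysine itself, and the 15 residues
downstream.  Near a protein terminus the missing positions are filled by
the mirror effect: the window is reflected about the terminal residue, so a
nominal position ``p < 1`` resolves to ``2 - p`` and ``p > L`` to
``2L - p``, applied iteratively for proteins shorter than the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import PSSMatrix, StructuralProfile

DEFAULT_FLANK = 15

#: Column order of the per-window structural track matrix.
STRUCT_TRACKS = ("asa", "ph", "pe", "pc", "phi", "psi", "theta", "tau")


class WindowError(ValueError):
    pass


@dataclass
class PeptideWindow:
    """Resolved 1-based residue indices of a peptide window.

    ``resolved_indices[flank]`` is always the central lysine;
    ``padded_flags`` marks slots that were mirror-mapped.
    """

    protein_id: str
    center: int
    length: int
    resolved_indices: np.ndarray
    padded_flags: np.ndarray
    flank: int = DEFAULT_FLANK

    @property
    def size(self) -> int:
        return 2 * self.flank + 1


def _reflect_terminus(p: int, L: int) -> int:
    # iterate for proteins shorter than the window; terminates for L >= 2
    while p < 1 or p > L:
        if p < 1:
            p = 2 - p
        else:
            p = 2 * L - p
    return p


def window_indices(
    L: int,
    center: int,
    flank: int = DEFAULT_FLANK,
    padding: str = "mirror-terminus",
    protein_id: str = "",
) -> PeptideWindow:
    """Resolve the window of ``2*flank + 1`` positions around ``center``.

    Parameters
    ----------
    L : int
        Protein length (must be >= 2 so reflection is well defined).
    center : int
        1-based position of the central residue.
    padding : {"mirror-terminus", "mirror-center"}
        ``mirror-terminus`` (default) reflects out-of-range positions about
        the nearest terminal residue.  ``mirror-center`` first tries the
        reflection about the central residue and falls back to the terminus
        rule; it exists for sensitivity checks only.
    """
    if L < 2:
        raise WindowError(f"protein of length {L} cannot be mirror-padded")
    if not 1 <= center <= L:
        raise WindowError(f"center {center} outside [1, {L}]")
    if flank < 1:
        raise WindowError("flank must be >= 1")
    if padding not in ("mirror-terminus", "mirror-center"):
        raise ValueError(f"unknown padding mode {padding!r}")

    slots = np.arange(-flank, flank + 1)
    nominal = center + slots
    resolved = np.empty_like(nominal)
    for j, p in enumerate(nominal):
        if 1 <= p <= L:
            resolved[j] = p
            continue
        if padding == "mirror-center":
            q = 2 * center - p
            resolved[j] = q if 1 <= q <= L else _reflect_terminus(int(p), L)
        else:
            resolved[j] = _reflect_terminus(int(p), L)
    flags = resolved != nominal
    return PeptideWindow(
        protein_id=protein_id,
        center=center,
        length=L,
        resolved_indices=resolved,
        padded_flags=flags,
        flank=flank,
    )


def extract_window_tracks(
    window: PeptideWindow, pssm: PSSMatrix, profile: StructuralProfile
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gather per-residue tracks along a resolved window.

    Returns ``(window_pssm, window_ss, window_struct)`` with shapes
    (W, 20), (W, 3) and (W, 8) for a window of W residues.  Structural
    columns are ordered as :data:`STRUCT_TRACKS`:
    (ASA, ph, pe, pc, phi, psi, theta, tau).
    """
    if len(pssm) != window.length or len(profile) != window.length:
        raise WindowError(
            f"track lengths (pssm={len(pssm)}, profile={len(profile)}) do not "
            f"match window protein length {window.length}"
        )
    rows = window.resolved_indices - 1  # to 0-based
    window_pssm = pssm.values[rows]
    window_ss = profile.ss_probs[rows]
    window_struct = np.column_stack(
        [profile.asa[rows], profile.ss_probs[rows], profile.angles[rows]]
    )
    return window_pssm, window_ss, window_struct
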
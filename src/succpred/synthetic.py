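"""Synthetic proteins, profiles and site annotations for end-to-end testing.

The generator emulates the four external inputs of the pipeline — FASTA
sequences, PSI-BLAST-style PSSMs, SPD3-style structural profiles and a
site-annotation table — with a tunable class-conditional signal.  It makes
the full pipeline testable without running PSI-BLAST or a structure
predictor, and its effect size ``delta`` controls exactly how separable the
two classes are:

* sequences are uniform over the 20 amino acids with lysines planted at
  every annotated site;
* PSSM rows are symmetric-Dirichlet probability vectors; inside the window
  flank of a *positive* site each row is mixed with a fixed motif vector at
  weight ``delta`` (``delta=0``: classes identically distributed;
  ``delta=1``: motif exactly);
* ASA is half-normal, secondary-structure rows are Dirichlet(1,1,1), and
  both are delta-mixed toward class-specific targets inside positive
  flanks; backbone angles stay uniform in [-180, 180] and carry no signal,
  so ablations can attribute performance to specific blocks.

Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    AA_ORDER,
    PSSMatrix,
    ProteinRecord,
    StructuralProfile,
    write_fasta,
    write_pssm,
    write_sites,
    write_structural_profile,
)
from .windows import DEFAULT_FLANK

#: Default motif: succinylation-like bias toward acidic residues (D, E)
#: with the rest of the mass spread uniformly.
def default_motif() -> np.ndarray:
    motif = np.full(20, 0.4 / 18)
    motif[AA_ORDER.index("D")] = 0.3
    motif[AA_ORDER.index("E")] = 0.3
    return motif


#: Structural targets for positive windows (helix-rich, exposed).
POSITIVE_SS_TARGET = np.array([0.70, 0.20, 0.10])  # (ph, pe, pc)
POSITIVE_ASA_TARGET = 120.0  # square Angstroms
ASA_SCALE = 50.0  # half-normal scale of background ASA


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults give a balanced 300+300 study set.

    Sites are placed at least one full window apart (``2*flank + 1``
    residues), so each site's window is class-pure: positive windows carry
    the delta-mixed signal, negative windows never overlap it.  The default
    protein count and length range provide enough such slots for the
    default 600 sites.
    """

    n_proteins: int = 60
    length_range: tuple[int, int] = (250, 500)
    n_pos: int = 300
    n_neg: int = 300
    effect_size: float = 0.5  # delta in [0, 1]
    motif: np.ndarray = field(default_factory=default_motif)
    background_concentration: float = 1.0
    flank: int = DEFAULT_FLANK
    seed: int = 0

    def __post_init__(self) -> None:
        self.motif = np.asarray(self.motif, dtype=float)
        if self.motif.shape != (20,) or abs(self.motif.sum() - 1.0) > 1e-9:
            raise SyntheticError("motif must be a 20-vector summing to 1")
        if not 0.0 <= self.effect_size <= 1.0:
            raise SyntheticError("effect_size must lie in [0, 1]")
        lo, hi = self.length_range
        if lo < 2 * self.flank + 2 or hi < lo:
            raise SyntheticError(
                f"protein lengths must be >= {2 * self.flank + 2} "
                f"and ordered, got {self.length_range}"
            )


@dataclass
class SyntheticData:
    records: list[ProteinRecord]
    pssms: dict[str, PSSMatrix]
    profiles: dict[str, StructuralProfile]
    sites: dict[str, list[tuple[int, int]]]


def _place_sites(
    rng: np.random.Generator, lengths: list[int], n_sites: int, min_sep: int
) -> list[list[int]]:
    """Distribute site positions over proteins, ``min_sep`` residues apart.

    Positions are drawn from a randomly offset grid of spacing ``min_sep``
    per protein, which keeps any two windows of flank (min_sep-1)/2
    non-overlapping while still exercising the terminus-padding path
    (offsets can fall on position 1).
    """
    n_proteins = len(lengths)
    grids = []
    for L in lengths:
        start = int(rng.integers(1, min_sep + 1))
        grids.append(np.arange(start, L + 1, min_sep))
    capacity = [g.size for g in grids]
    if n_sites > sum(capacity):
        raise SyntheticError(
            f"cannot place {n_sites} sites {min_sep} residues apart in "
            f"{n_proteins} proteins of these lengths"
        )
    counts = rng.multinomial(n_sites, np.asarray(capacity) / sum(capacity))
    counts = np.minimum(counts, capacity)
    remainder = n_sites - int(counts.sum())
    i = 0
    while remainder > 0:
        if counts[i] < capacity[i]:
            counts[i] += 1
            remainder -= 1
        i = (i + 1) % n_proteins
    placed: list[list[int]] = []
    for grid, c in zip(grids, counts):
        chosen = rng.choice(grid, size=int(c), replace=False)
        placed.append(sorted(int(p) for p in chosen))
    return placed


def generate(config: SyntheticConfig) -> SyntheticData:
    """Draw a fully reproducible synthetic study set from ``config``."""
    rng = np.random.default_rng(config.seed)
    delta = config.effect_size
    lo, hi = config.length_range
    lengths = [int(L) for L in rng.integers(lo, hi + 1, size=config.n_proteins)]

    # assign positive and negative sites to window-disjoint positions
    all_positions = _place_sites(
        rng, lengths, config.n_pos + config.n_neg, min_sep=2 * config.flank + 1
    )
    records: list[ProteinRecord] = []
    pssms: dict[str, PSSMatrix] = {}
    profiles: dict[str, StructuralProfile] = {}
    sites: dict[str, list[tuple[int, int]]] = {}

    # flatten, shuffle, split into positive/negative site labels
    flat = [(i, pos) for i, plist in enumerate(all_positions) for pos in plist]
    order = rng.permutation(len(flat))
    pos_keys = {tuple(flat[j]) for j in order[: config.n_pos]}

    alphabet = np.array(list(AA_ORDER))
    alpha = np.full(20, config.background_concentration)
    for i, L in enumerate(lengths):
        pid = f"synth{i + 1:03d}"
        seq = alphabet[rng.integers(0, 20, size=L)]
        site_list = []
        pos_positions = []
        for pos in all_positions[i]:
            seq[pos - 1] = "K"
            label = 1 if (i, pos) in pos_keys else -1
            site_list.append((int(pos), label))
            if label == 1:
                pos_positions.append(int(pos))

        pssm = rng.dirichlet(alpha, size=L)
        asa = np.abs(rng.normal(0.0, ASA_SCALE, size=L))
        ss = rng.dirichlet(np.ones(3), size=L)  # (ph, pe, pc)
        angles = rng.uniform(-180.0, 180.0, size=(L, 4))

        # class-conditional signal: delta-mix rows inside positive flanks
        if delta > 0.0:
            for pos in pos_positions:
                sl = slice(max(0, pos - 1 - config.flank), min(L, pos + config.flank))
                pssm[sl] = (1.0 - delta) * pssm[sl] + delta * config.motif
                ss[sl] = (1.0 - delta) * ss[sl] + delta * POSITIVE_SS_TARGET
                asa[sl] = (1.0 - delta) * asa[sl] + delta * POSITIVE_ASA_TARGET

        records.append(ProteinRecord(id=pid, sequence="".join(seq), sites=site_list))
        pssms[pid] = PSSMatrix(protein_id=pid, values=pssm)
        profiles[pid] = StructuralProfile(
            protein_id=pid, asa=asa, ss_probs=ss, angles=angles
        )
        sites[pid] = site_list
    return SyntheticData(records=records, pssms=pssms, profiles=profiles, sites=sites)


def write_fixture_set(data: SyntheticData, directory) -> dict[str, str]:
    """Write a generated set as the on-disk formats the parsers read.

    Emits ``proteins.fasta``, ``sites.tsv``, and per-protein
    ``<id>.pssm`` / ``<id>.spd3`` files.  PSSM percentages are written as
    integers (the real dialect), so re-reading quantizes probabilities to
    0.01 resolution.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "proteins.fasta"
    sites_path = directory / "sites.tsv"
    write_fasta(data.records, fasta)
    write_sites(data.sites, sites_path)
    for pid, pssm in data.pssms.items():
        quantized = PSSMatrix(
            protein_id=pid, values=np.round(pssm.values * 100) / 100.0
        )
        write_pssm(quantized, directory / f"{pid}.pssm")
    for pid, profile in data.profiles.items():
        write_structural_profile(profile, directory / f"{pid}.spd3")
    return {
        "fasta": str(fasta),
        "sites": str(sites_path),
        "pssm_dir": str(directory),
        "spd3_dir": str(directory),
    }
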
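"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one of the screen's data sources: a proteome with
planted motif sites (for the PWM scan), a cohort of genes with evidence
annotations and site profiles (for candidate filtering), dilution-spot
growth matrices constructed to a target grade (for the SDL rubric), and
m/z peak lists with additive ppm error (for targeted identification).
All generators are deterministic for a fixed seed; each draws from its own
named pseudo-random stream so adding a generator never shifts the outputs
of another.

Construction guarantees that make the adjoint tests exact rather than
probabilistic:

* planted windows contain exactly one S/T (the acceptor) and accidental
  core-constraint windows anywhere in the background are repaired away, so
  a core-mode scan recovers exactly the planted sites;
* in the evidence cohort every non-candidate fails only the evidence gate,
  so the candidate label is a deterministic function of the gate flag and
  the analytic label-recovery accuracy under gate flips is 1 - flip_rate;
* noise peaks are rejected within 5x the matching tolerance of any target,
  so they are never matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .motif import AMINO_ACIDS, AA_INDEX, DEFAULT_OFFSETS, HYDROPHOBIC_PLUS1, MotifWindow, SiteScore
from .scan import ProteinRecord, SiteHit, extract_window
from .sdl import INHIBITOR_UM, SDLGrade, SDLGrowthRecord, Condition
from .evidence import EvidenceRecord
from .lipids import MassTarget, default_targets

# fixed stream ids so generators have independent, stable streams
_STREAMS = {"proteome": 1, "evidence": 2, "growth": 3, "peaks": 4}

#: average proteome residue composition (Swiss-Prot statistics), order ACDEFGHIKLMNPQRSTVWY
AVERAGE_COMPOSITION: dict[str, float] = {
    "A": 8.25, "C": 1.38, "D": 5.46, "E": 6.72, "F": 3.86,
    "G": 7.08, "H": 2.27, "I": 5.91, "K": 5.80, "L": 9.65,
    "M": 2.41, "N": 4.06, "P": 4.74, "Q": 3.93, "R": 5.53,
    "S": 6.64, "T": 5.35, "V": 6.86, "W": 1.10, "Y": 2.92,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([_STREAMS[stream], int(seed)]))


def default_background() -> np.ndarray:
    """Average proteome composition as a normalised 20-vector."""
    v = np.array([AVERAGE_COMPOSITION[a] for a in AMINO_ACIDS])
    return v / v.sum()


@dataclass(frozen=True)
class PlantedSite:
    protein_id: str
    position: int  # 1-based acceptor position
    strict_conforming: bool


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation run."""

    seed: int
    planted_sites: list[PlantedSite] = field(default_factory=list)
    candidate_labels: dict[str, bool] = field(default_factory=dict)
    intended_grades: dict[str, SDLGrade] = field(default_factory=dict)
    spiked_species: list[tuple[str, float, float]] = field(default_factory=list)


# -- proteome with planted motifs ------------------------------------------

# residues that can never contribute to a core motif: no acceptor, no Arg
_SAFE = [a for a in AMINO_ACIDS if a not in "STR"]
_SAFE_NONHYD = [a for a in _SAFE if a not in HYDROPHOBIC_PLUS1]


def _planted_window(rng: np.random.Generator, strict: bool, offsets: Sequence[int]) -> dict[int, str]:
    """Residues of a planted window: invariant Arg at -5/-3, one acceptor,
    +1 hydrophobic iff strict, everything else from the safe alphabet."""
    residues: dict[int, str] = {}
    for o in offsets:
        if o == -5 or o == -3:
            residues[o] = "R"
        elif o == 0:
            residues[o] = str(rng.choice(["S", "T"]))
        elif o == 1:
            residues[o] = str(
                rng.choice(sorted(HYDROPHOBIC_PLUS1)) if strict else rng.choice(_SAFE_NONHYD)
            )
        else:
            residues[o] = str(rng.choice(_SAFE))
    return residues


def generate_proteome(
    n_proteins: int = 20,
    length_range: tuple[int, int] = (200, 500),
    n_strict: int = 0,
    n_core: int = 0,
    background: np.ndarray | None = None,
    seed: int = 0,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Simulate a proteome of i.i.d.-background proteins with planted
    motif sites.

    ``n_strict`` sites conform to the full motif (hydrophobic +1),
    ``n_core`` only to the invariant core.  Accidental core-constraint
    windows in the background are repaired (their acceptor is mutated), so
    scanning recovers exactly the planted sites.
    """
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    rng = _rng(seed, "proteome")
    bg = default_background() if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n_proteins)
    span = max(offsets) - min(offsets) + 1
    min_len_needed = span + 2
    lengths = np.maximum(lengths, min_len_needed)

    aa = np.array(list(AMINO_ACIDS))
    sequences = [list(aa[rng.choice(20, size=int(L), p=bg)]) for L in lengths]
    ids = [f"sprot{i:04d}" for i in range(n_proteins)]

    # round-robin assignment of planted sites to proteins
    flags = [True] * n_strict + [False] * n_core
    planted: list[PlantedSite] = []
    occupied: dict[int, list[int]] = {i: [] for i in range(n_proteins)}
    for k, strict in enumerate(flags):
        pi = k % n_proteins
        seq = sequences[pi]
        L = len(seq)
        placed = False
        for _ in range(200):
            pos = int(rng.integers(1 - min(offsets), L - max(offsets) + 1))  # 1-based
            if all(abs(pos - q) >= span + 5 for q in occupied[pi]):
                placed = True
                break
        if not placed:
            raise ValueError(f"could not place planted site {k} in protein {ids[pi]}")
        occupied[pi].append(pos)
        for o, r in _planted_window(rng, strict, offsets).items():
            seq[pos - 1 + o] = r
        planted.append(PlantedSite(ids[pi], pos, strict))

    # repair pass: mutate the acceptor of any accidental core motif
    planted_positions = {(s.protein_id, s.position) for s in planted}
    for pi, seq in enumerate(sequences):
        for p in range(1, len(seq) + 1):
            if seq[p - 1] not in "ST" or (ids[pi], p) in planted_positions:
                continue
            if p - 5 >= 1 and seq[p - 6] == "R" and seq[p - 4] == "R":
                seq[p - 1] = str(rng.choice(_SAFE))

    proteins = [
        ProteinRecord(ids[i], f"synthetic protein {i}", "".join(sequences[i]))
        for i in range(n_proteins)
    ]
    truth = SyntheticTruth(seed=seed, planted_sites=sorted(planted, key=lambda s: (s.protein_id, s.position)))
    return proteins, truth


# -- evidence cohort --------------------------------------------------------


@dataclass
class EvidenceCohort:
    """Genes with evidence records, pseudo site hits and intended labels."""

    evidence: list[EvidenceRecord]
    hits: list[SiteHit]
    labels: dict[str, bool]  # intended is_candidate
    branches: dict[str, str]  # intended branch for candidates (a/b/c)


def _pseudo_hit(gene: str, position: int, likelihood: float) -> SiteHit:
    window = MotifWindow.from_string("RARAQSVKAE", DEFAULT_OFFSETS)
    score = SiteScore(raw_logodds=likelihood, likelihood=likelihood, core_ok=True, plus1_hydrophobic=True)
    return SiteHit(gene, position, window, score)


def generate_evidence(
    n_genes: int = 200,
    flip_rate: float = 0.0,
    seed: int = 0,
    likelihood_cutoff: float = 0.7,
) -> EvidenceCohort:
    """Simulate a candidate cohort for the (a)/(b)/(c) filtering rules.

    Intended candidates (half the cohort) cycle through branches a, b and
    c with gate evidence present; intended non-candidates carry the same
    site profiles but no gate evidence, so every label flip is driven by
    the gate alone.  With probability ``flip_rate`` a gene's gate evidence
    is toggled, flipping its recovered label.
    """
    if not 0.0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must be in [0, 0.5)")
    rng = _rng(seed, "evidence")
    evidence: list[EvidenceRecord] = []
    hits: list[SiteHit] = []
    labels: dict[str, bool] = {}
    branches: dict[str, str] = {}
    go_terms = ["Lipid Metabolic Process", "Signaling", "Translation", "Biological Process Unknown"]
    for i in range(n_genes):
        gene = f"sgene{i:04d}"
        intended_candidate = i % 2 == 0
        branch = "abc"[(i // 2) % 3]
        labels[gene] = intended_candidate
        branches[gene] = branch if intended_candidate else "none"

        # site profile satisfying the intended branch
        phosphogrid: set[int] = set()
        if branch == "a":
            n_sites = int(rng.integers(4, 7))
            liks = rng.uniform(0.0, 1.0, size=n_sites)
        elif branch == "b":
            n_sites = 3
            liks = rng.uniform(0.0, likelihood_cutoff, size=n_sites)
            if rng.random() < 0.5:
                liks[int(rng.integers(n_sites))] = float(rng.uniform(likelihood_cutoff + 0.01, 1.0))
            else:
                phosphogrid.add(1)  # flag: mark the first emitted site below
        else:  # branch c
            n_sites = int(rng.integers(1, 3))
            liks = rng.uniform(0.0, likelihood_cutoff - 0.05, size=n_sites)
            liks[int(rng.integers(n_sites))] = float(rng.uniform(likelihood_cutoff, 1.0))
            phosphogrid.add(1)
        positions = sorted(rng.choice(np.arange(10, 900), size=n_sites, replace=False).tolist())
        pg_positions = frozenset({int(positions[0])}) if phosphogrid else frozenset()
        hits.extend(_pseudo_hit(gene, int(p), float(l)) for p, l in zip(positions, liks))

        gate = intended_candidate
        if rng.random() < flip_rate:
            gate = not gate
        phen: frozenset[str] = frozenset()
        interaction = False
        if gate:
            if rng.random() < 0.5:
                interaction = True
            else:
                phen = frozenset(
                    rng.choice(["myriocin", "aureobasidinA", "caspofungin"],
                               size=int(rng.integers(1, 3)), replace=False).tolist()
                )
        evidence.append(
            EvidenceRecord(
                gene_id=gene,
                phenotypes=phen,
                interaction=interaction,
                phosphogrid_positions=pg_positions,
                go_slim=go_terms[i % len(go_terms)],
            )
        )
    return EvidenceCohort(evidence=evidence, hits=hits, labels=labels, branches=branches)


# -- growth matrices to a target grade --------------------------------------


def generate_growth_matrices(
    intended_grades: Mapping[str, SDLGrade],
    n_dilutions: int = 5,
    seed: int = 0,
) -> tuple[list[SDLGrowthRecord], SyntheticTruth]:
    """Construct growth records whose rubric grade equals the intent.

    Controls grow the full series everywhere; dextrose growth of the gene
    construct matches its control (no baseline toxicity) except for TOXIC
    intent, where the wild-type strain is impaired on galactose without
    inhibitor.  NA intent omits the galactose cells.
    """
    rng = _rng(seed, "growth")
    n = n_dilutions
    records: list[SDLGrowthRecord] = []
    for gene, grade in intended_grades.items():
        control: dict[Condition, int] = {}
        growth: dict[Condition, int] = {}
        for strain in ("analog_sensitive", "wild_type"):
            for carbon in ("dextrose", "galactose"):
                for conc in INHIBITOR_UM:
                    control[(strain, carbon, conc)] = n
                    growth[(strain, carbon, conc)] = n

        def set_gal(g0: int, g1: int, g2: int) -> None:
            growth[("analog_sensitive", "galactose", 0)] = g0
            growth[("analog_sensitive", "galactose", 1)] = g1
            growth[("analog_sensitive", "galactose", 2)] = g2

        if grade is SDLGrade.MINUS:
            set_gal(n, n, n)
        elif grade is SDLGrade.P1:
            set_gal(n, n, int(rng.integers(1, n)))
        elif grade is SDLGrade.P2:
            set_gal(n, n, 0)
        elif grade is SDLGrade.P3:
            g1 = int(rng.integers(1, n))
            set_gal(n, g1, int(rng.integers(0, g1 + 1)))
        elif grade is SDLGrade.P4:
            set_gal(n, 0, 0)
        elif grade is SDLGrade.P5:
            g0 = int(rng.integers(0, n))
            g1 = int(rng.integers(0, g0 + 1))
            set_gal(g0, g1, int(rng.integers(0, g1 + 1)))
        elif grade is SDLGrade.TOXIC:
            deficit = int(rng.integers(1, n + 1))
            growth[("wild_type", "galactose", 0)] = n - deficit
            set_gal(int(rng.integers(0, n + 1)), int(rng.integers(0, n + 1)), int(rng.integers(0, n + 1)))
        elif grade is SDLGrade.NA:
            for cond in list(growth):
                if cond[1] == "galactose":
                    del growth[cond]
                    del control[cond]
        else:  # pragma: no cover
            raise ValueError(f"unknown grade {grade}")
        records.append(SDLGrowthRecord(gene, growth, control, n_dilutions=n))
    truth = SyntheticTruth(seed=seed, intended_grades=dict(intended_grades))
    return records, truth


# -- peak lists -------------------------------------------------------------


def generate_peaklist(
    species_targets: Sequence[MassTarget] | None = None,
    error_ppm_sd: float = 2.0,
    n_noise_peaks: int = 5,
    seed: int = 0,
    tol_ppm: float = 10.0,
) -> tuple[list[float], SyntheticTruth]:
    """One peak per target perturbed by Gaussian ppm error, plus uniform
    noise peaks constrained to lie more than ``5 * tol_ppm`` from every
    target so they can never be matched at the default tolerance."""
    if error_ppm_sd < 0:
        raise ValueError("error sd must be nonnegative")
    rng = _rng(seed, "peaks")
    targets = list(default_targets() if species_targets is None else species_targets)
    truth = SyntheticTruth(seed=seed)
    peaks: list[float] = []
    for t in targets:
        err = float(rng.normal(0.0, error_ppm_sd)) if error_ppm_sd > 0 else 0.0
        mz = t.precursor_mz * (1.0 + err * 1e-6)
        peaks.append(mz)
        truth.spiked_species.append((t.species.name, t.precursor_mz, err))
    mzs = [t.precursor_mz for t in targets]
    lo, hi = min(mzs) - 50.0, max(mzs) + 50.0
    added = 0
    while added < n_noise_peaks:
        mz = float(rng.uniform(lo, hi))
        if all(abs(mz - t) / t * 1e6 > 5 * tol_ppm for t in mzs):
            peaks.append(mz)
            added += 1
    return peaks, truth
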
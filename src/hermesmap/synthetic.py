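"""Synthetic ground-truth inputs for the pipeline.

Three generators emulate the statistical structure of the study inputs so
every downstream stage has a known-answer input:

* ``generate_proteome`` — random protein databases containing redundancy
  families (homologues, truncations, splice variants) so that parsimony
  inference is non-degenerate;
* ``generate_psm_tables`` — spectral sampling: per replicate a Poisson total
  spectrum count allocated multinomially over proteins by relative abundance,
  then uniformly over each protein's tryptic peptides;
* ``generate_gold_scenes`` — immunogold micrograph scenes with particles
  placed on plasma membrane / cisternae / flagellum traces and displaced by
  isotropic Gaussian localisation jitter.

Every random draw flows from a single top-level seed through a documented
stream-splitting rule: stage ``name`` with sub-key ``k`` uses
``numpy.random.SeedSequence(seed, spawn_key=(STAGE[name], *k))``, so stages
(and individual replicates or scenes) can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, GenerationError, ParameterError
from .goldquant import GoldScene, Particle, Structure

__all__ = [
    "GroundTruthProteome",
    "FractionDesign",
    "SyntheticGoldDesign",
    "DEFAULT_FRACTIONS",
    "digest",
    "generate_proteome",
    "planted_abundance",
    "generate_psm_tables",
    "generate_gold_scenes",
    "stage_rng",
]

#: the five subcellular fractions profiled in the study
DEFAULT_FRACTIONS = ("HermesBody", "TestisGolgi", "LiverGolgi", "LiverER", "COPI")

#: stage indices of the seed-splitting rule
_STAGE = {"proteome": 0, "psm": 1, "gold": 2, "abundance": 3, "annotation": 4}

_AA = "ACDEFGHIKLMNPQRSTVWY"
# residue frequencies tuned so fully tryptic 6-30-mers are common:
# K and R at 6% each, P at 2%, the rest uniform
_AA_P = np.full(20, (1.0 - 0.06 * 2 - 0.02) / 17)
_AA_P[_AA.index("K")] = 0.06
_AA_P[_AA.index("R")] = 0.06
_AA_P[_AA.index("P")] = 0.02

DEFAULT_MIN_LEN = 6
DEFAULT_MAX_LEN = 30


def stage_rng(seed: int, stage: str, *sub: int) -> np.random.Generator:
    """Child generator for one stage (and optional sub-stream) of a run."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGE[stage], *sub))
    )


# ---------------------------------------------------------------------------
# tryptic digest
# ---------------------------------------------------------------------------

def digest(
    sequence: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[str]:
    """Fully cleaved tryptic peptides of ``sequence`` within a length window.

    Cleaves after K or R except when the next residue is P (no missed
    cleavages). Peptides are returned in sequence order; with ``min_len=1``
    and a large ``max_len`` they partition the sequence exactly.
    """
    if not sequence:
        raise FormatError("empty sequence")
    if not sequence.isupper() or not sequence.isalpha():
        bad = next(c for c in sequence if not (c.isupper() and c.isalpha()))
        raise FormatError(f"invalid residue {bad!r}")
    peptides: list[str] = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            peptides.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        peptides.append(sequence[start:])
    return [p for p in peptides if min_len <= len(p) <= max_len]


# ---------------------------------------------------------------------------
# ground-truth proteome
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthProteome:
    """A synthetic protein database with known redundancy structure."""

    proteins: list[tuple[str, str]]
    families: list[frozenset[str]]
    peptide_map: dict[str, frozenset[str]]
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN

    def sequence(self, accession: str) -> str:
        return dict(self.proteins)[accession]

    def peptides_of(self, accession: str) -> list[str]:
        return digest(self.sequence(accession), self.min_len, self.max_len)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_AA))[rng.choice(20, size=length, p=_AA_P)])


def _truncation(base: str) -> str:
    # prefix ending on a cleavage site past ~60% of the sequence, so the
    # truncated form shares complete tryptic peptides with its parent
    cut = int(len(base) * 0.6)
    while cut < len(base) - 1 and not (
        base[cut] in "KR" and base[cut + 1] != "P"
    ):
        cut += 1
    return base[: cut + 1]

def _splice_variant(base: str) -> str:
    # delete one internal exon-like block (~30% of the sequence)
    a = int(len(base) * 0.35)
    b = int(len(base) * 0.65)
    return base[:a] + base[b:]

def _homolog(base: str, rng: np.random.Generator) -> str:
    # replace the C-terminal third with fresh sequence: shared N-terminal
    # peptides, distinct C-terminal ones
    keep = int(len(base) * 0.67)
    return base[:keep] + _random_sequence(rng, len(base) - keep)


def generate_proteome(
    n_proteins: int,
    n_families: int,
    seed: int,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> GroundTruthProteome:
    """Random proteome with ``n_families`` two-member redundancy families.

    Family variants cycle through truncation (a sequence prefix), splice
    variant (internal block deletion) and homologue (shared N-terminal
    region). Deterministic for a fixed seed.
    """
    if n_proteins < 2:
        raise ParameterError("n_proteins must be >= 2")
    if n_families < 0 or 2 * n_families > n_proteins:
        raise ParameterError("need 0 <= 2*n_families <= n_proteins")

    rng = stage_rng(seed, "proteome")
    sequences: list[str] = []
    while len(sequences) < n_proteins:
        seq = _random_sequence(rng, int(rng.integers(180, 400)))
        if digest(seq, min_len, max_len):  # every protein must yield peptides
            sequences.append(seq)

    variant_kinds = ("truncation", "splice", "homolog")
    families: list[frozenset[str]] = []
    for f in range(n_families):
        base_i, var_i = 2 * f, 2 * f + 1
        kind = variant_kinds[f % 3]
        base = sequences[base_i]
        if kind == "truncation":
            var = _truncation(base)
        elif kind == "splice":
            var = _splice_variant(base)
        else:
            var = _homolog(base, rng)
        if not digest(var, min_len, max_len):
            var = _truncation(base)
        sequences[var_i] = var
        families.append(frozenset({f"P{base_i:04d}", f"P{var_i:04d}"}))

    proteins = [(f"P{i:04d}", seq) for i, seq in enumerate(sequences)]
    peptide_map: dict[str, frozenset[str]] = {}
    all_peps = {p for _, seq in proteins for p in digest(seq, min_len, max_len)}
    for pep in sorted(all_peps):
        peptide_map[pep] = frozenset(acc for acc, seq in proteins if pep in seq)
    return GroundTruthProteome(proteins, families, peptide_map, min_len, max_len)


# ---------------------------------------------------------------------------
# fraction design and PSM sampling
# ---------------------------------------------------------------------------

@dataclass
class FractionDesign:
    """Per-fraction relative abundance design for spectral sampling.

    ``abundance`` maps each accession to one relative abundance per fraction
    (columns sum to 1). ``replicates`` biological repeats per fraction (3 or
    4 in the study), ``depth`` the expected total spectra per replicate.
    """

    fraction_names: tuple[str, ...]
    abundance: Mapping[str, Sequence[float]]
    replicates: int = 3
    depth: int = 10_000
    seed: int = 0
    min_confidence: float = 0.95

    def __post_init__(self):
        if not 1 <= self.replicates <= 10:
            raise ParameterError("replicates must be in 1..10")
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        cols = np.array([list(v) for v in self.abundance.values()], dtype=float)
        if cols.shape[1] != len(self.fraction_names):
            raise ParameterError("abundance rows must match fraction_names")
        if (cols < 0).any():
            raise ParameterError("abundance must be non-negative")
        sums = cols.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ParameterError(f"abundance columns must sum to 1, got {sums}")


def planted_abundance(
    accessions: Sequence[str],
    fraction_names: Sequence[str] = DEFAULT_FRACTIONS,
    target: str = "HermesBody",
    n_target_enriched: int = 10,
    n_reference_enriched: int = 10,
    fold: float = 8.0,
    seed: int = 0,
) -> tuple[dict[str, list[float]], dict[str, str]]:
    """Abundance design with planted enrichment classes.

    The first ``n_target_enriched`` accessions are ``fold`` times more
    abundant in the target fraction than elsewhere, the next
    ``n_reference_enriched`` are ``fold`` times more abundant in every
    reference fraction, and the rest are flat. Returns the per-fraction
    abundance map and the ground-truth class of each accession
    (``enriched`` / ``depleted`` / ``flat`` relative to the target).
    """
    if n_target_enriched + n_reference_enriched > len(accessions):
        raise ParameterError("more planted proteins than accessions")
    if target not in fraction_names:
        raise ParameterError(f"target {target!r} not in fraction_names")
    t = list(fraction_names).index(target)
    weights = np.ones((len(accessions), len(fraction_names)))
    truth: dict[str, str] = {}
    for i, acc in enumerate(accessions):
        if i < n_target_enriched:
            weights[i, t] = fold
            truth[acc] = "enriched"
        elif i < n_target_enriched + n_reference_enriched:
            weights[i, :] = fold
            weights[i, t] = 1.0
            truth[acc] = "depleted"
        else:
            truth[acc] = "flat"
    weights /= weights.sum(axis=0, keepdims=True)
    abundance = {acc: list(weights[i]) for i, acc in enumerate(accessions)}
    return abundance, truth


def generate_psm_tables(
    proteome: GroundTruthProteome,
    design: FractionDesign,
) -> dict[tuple[str, int], pd.DataFrame]:
    """Sample PSM tables, one per fraction x replicate.

    Per replicate the total spectrum count is Poisson(depth); spectra are
    allocated to proteins multinomially by the fraction's abundance column
    and to each protein's tryptic peptides uniformly. Every PSM carries a
    confidence at or above the design's threshold (scoring itself is not
    simulated). Deterministic for a fixed seed.
    """
    accs = list(design.abundance.keys())
    known = {acc for acc, _ in proteome.proteins}
    for acc in accs:
        if acc not in known:
            raise ParameterError(f"accession {acc} not in proteome")
    peptides_by_acc = {}
    for acc in accs:
        peps = proteome.peptides_of(acc)
        if not peps:
            raise GenerationError(
                f"protein {acc} has no peptides in length range "
                f"{proteome.min_len}-{proteome.max_len}"
            )
        peptides_by_acc[acc] = peps

    probs = np.array([list(design.abundance[acc]) for acc in accs], dtype=float)
    tables: dict[tuple[str, int], pd.DataFrame] = {}
    for j, fraction in enumerate(design.fraction_names):
        for rep in range(1, design.replicates + 1):
            rng = stage_rng(design.seed, "psm", j, rep)
            total = int(rng.poisson(design.depth))
            per_protein = rng.multinomial(total, probs[:, j]) if total else np.zeros(
                len(accs), dtype=int
            )
            pep_col: list[str] = []
            for acc, count in zip(accs, per_protein):
                if count == 0:
                    continue
                peps = peptides_by_acc[acc]
                per_pep = rng.multinomial(count, np.full(len(peps), 1 / len(peps)))
                for pep, c in zip(peps, per_pep):
                    pep_col.extend([pep] * int(c))
            conf = design.min_confidence + (1 - design.min_confidence) * rng.random(
                len(pep_col)
            )
            tables[(fraction, rep)] = pd.DataFrame(
                {
                    "peptide": pep_col,
                    "sample": fraction,
                    "replicate": rep,
                    "confidence": np.round(conf, 6),
                }
            )
    return tables


# ---------------------------------------------------------------------------
# immunogold scenes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGoldDesign:
    """Design of a batch of synthetic immunogold scenes.

    ``compartment_fractions`` gives the ground-truth proportion of particles
    generated on each structural compartment (keys ``plasma_membrane``,
    ``cisterna``, ``flagellum``); ``jitter_sd`` the isotropic Gaussian
    localisation displacement in nm (default 10, the order of the
    antibody-gold displacement for 12 nm particles); ``control_fraction``
    the fraction of micrographs imaged without primary antibody.
    """

    compartment_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "plasma_membrane": 0.21,
            "cisterna": 0.67,
            "flagellum": 0.12,
        }
    )
    n_particles: int = 300
    n_micrographs: int = 10
    jitter_sd: float = 10.0
    dilutions: tuple[str, ...] = ("1:1", "1:5", "1:10")
    control_fraction: float = 0.0
    background_max: int = 3
    seed: int = 0

    def __post_init__(self):
        fr = self.compartment_fractions
        if set(fr) != {"plasma_membrane", "cisterna", "flagellum"}:
            raise ParameterError("compartment_fractions must key all 3 compartments")
        if not math.isclose(sum(fr.values()), 1.0, abs_tol=1e-9):
            raise ParameterError("compartment_fractions must sum to 1")
        if any(v < 0 for v in fr.values()):
            raise ParameterError("compartment_fractions must be non-negative")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be >= 0")
        if not 0 <= self.control_fraction <= 1:
            raise ParameterError("control_fraction must be in [0, 1]")
        n_controls = round(self.control_fraction * self.n_micrographs)
        if self.n_particles <= 0 and n_controls < self.n_micrographs:
            raise ParameterError("n_particles must be positive for non-control scenes")


def _ellipse(cx, cy, rx, ry, n=48) -> tuple[tuple[float, float], ...]:
    ang = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return tuple(
        (float(cx + rx * math.cos(a)), float(cy + ry * math.sin(a))) for a in ang
    )


def _scene_structures(rng: np.random.Generator) -> list[Structure]:
    """Hermes-body geometry: a ~2 um plasma-membrane profile enclosing three
    flattened cisternae and a flagellar cross-section, with >=150 nm clearance
    between structures so band classification is unambiguous at zero jitter."""
    pm_kind = "cross" if rng.random() < 0.7 else "oblique"
    fl_kind = "cross" if rng.random() < 0.7 else "oblique"
    structures = [
        Structure("plasma_membrane", pm_kind, _ellipse(1500, 1200, 1100, 950), True)
    ]
    for y in (700.0, 1000.0, 1300.0):
        xs = np.linspace(900, 2100, 13)
        ys = y + 30 * np.sin(np.linspace(0, math.pi, 13))
        structures.append(
            Structure(
                "cisterna",
                "cross",
                tuple((float(a), float(b)) for a, b in zip(xs, ys)),
                False,
            )
        )
    structures.append(
        Structure("flagellum", fl_kind, _ellipse(1500, 1800, 140, 140, 24), True)
    )
    return structures


def _point_on_polyline(
    rng: np.random.Generator, structure: Structure
) -> tuple[float, float]:
    pts = list(structure.points)
    if structure.closed:
        pts = pts + [pts[0]]
    seg = np.diff(np.array(pts), axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    i = rng.choice(len(lengths), p=lengths / lengths.sum())
    t = rng.random()
    x0, y0 = pts[i]
    return (x0 + t * seg[i, 0], y0 + t * seg[i, 1])


def generate_gold_scenes(design: SyntheticGoldDesign) -> list[GoldScene]:
    """Generate a batch of synthetic immunogold scenes.

    Each non-control scene places ``n_particles`` on a structure drawn by
    ``compartment_fractions``, uniformly along its trace by arc length, then
    displaces it by isotropic Gaussian jitter; the generating compartment is
    kept as a truth label. Control scenes carry only a small background count
    of uniformly scattered unlabelled particles. Scenes cycle through the
    configured dilutions and alternate between two animals.
    """
    comps = ("plasma_membrane", "cisterna", "flagellum")
    p = np.array([design.compartment_fractions[c] for c in comps])
    n_controls = round(design.control_fraction * design.n_micrographs)
    scenes: list[GoldScene] = []
    for i in range(design.n_micrographs):
        rng = stage_rng(design.seed, "gold", i)
        structures = _scene_structures(rng)
        is_control = i >= design.n_micrographs - n_controls
        particles: list[Particle] = []
        if is_control:
            n_bg = int(rng.integers(0, design.background_max + 1))
            for _ in range(n_bg):
                particles.append(
                    Particle(float(rng.uniform(200, 2800)), float(rng.uniform(100, 2300)))
                )
        else:
            by_comp = {c: [s for s in structures if s.compartment == c] for c in comps}
            labels = rng.choice(len(comps), size=design.n_particles, p=p)
            for lab in labels:
                comp = comps[lab]
                s = by_comp[comp][rng.integers(len(by_comp[comp]))]
                x, y = _point_on_polyline(rng, s)
                if design.jitter_sd > 0:
                    x += rng.normal(0, design.jitter_sd)
                    y += rng.normal(0, design.jitter_sd)
                particles.append(Particle(float(x), float(y), truth=comp))
        scenes.append(
            GoldScene(
                scene_id=f"scene{i:03d}",
                animal=f"rat{i % 2 + 1}",
                dilution=design.dilutions[i % len(design.dilutions)],
                is_control=is_control,
                structures=structures,
                particles=particles,
            )
        )
    return scenes
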
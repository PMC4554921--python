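"""Readers and writers for every on-disk format the pipeline touches.

Formats are deliberately plain: FASTA for protein databases, tab-separated
UTF-8 tables (``.`` decimal, no quoting) for PSMs, annotations, matrices and
reports, JSON for immunogold scenes, and Cluster-3.0-compatible CDT/GTR
files so clustered heat maps open in standard tree viewers.

All writers are deterministic: stable row order (proteins by descending
overall abundance, then accession) and stable column order (samples in
declared fraction order). Every reader validates strictly and raises
:class:`~hermesmap.errors.FormatError` with a location.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .errors import FormatError
from .goldquant import GoldScene, Particle, Structure
from .profiles import FUNCTIONAL_CATEGORIES, ClusterResult

log = logging.getLogger(__name__)

__all__ = [
    "PSMRecord",
    "DEFAULT_MIN_CONFIDENCE",
    "read_fasta",
    "write_fasta",
    "read_psm_table",
    "write_psm_table",
    "read_annotation",
    "write_annotation",
    "read_gold_scene",
    "write_gold_scene",
    "read_quant_matrix",
    "write_quant_matrix",
    "order_matrix",
    "write_cdt_gtr",
    "write_tsv",
]

#: default PSM confidence filter, mirroring 95% assignment confidence
DEFAULT_MIN_CONFIDENCE = 0.95

COORD_CONVENTION = "nm; origin at image top-left; y increases downward"


@dataclass(frozen=True)
class PSMRecord:
    """One scored peptide-spectrum match in one sample/replicate."""

    peptide: str
    sample: str
    replicate: int
    confidence: float

    def __post_init__(self):
        if not self.peptide:
            raise FormatError("empty peptide")
        if not 0.0 <= self.confidence <= 1.0:
            raise FormatError(f"confidence {self.confidence} outside [0, 1]")
        if self.replicate < 1:
            raise FormatError(f"replicate {self.replicate} must be >= 1")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read a protein database; accession = first header token, sequences
    uppercased, duplicate accessions rejected."""
    entries: list[tuple[str, str]] = []
    seen: set = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        seq = str(rec.seq).upper()
        if not acc or not seq:
            raise FormatError(f"{path}: empty FASTA record")
        if acc in seen:
            raise FormatError(f"{path}: duplicate accession {acc!r}")
        seen.add(acc)
        entries.append((acc, seq))
    if not entries:
        raise FormatError(f"{path}: no FASTA records")
    return entries


def write_fasta(entries: Sequence[tuple[str, str]], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc, seq in entries:
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

_PSM_COLUMNS = ("peptide", "sample", "replicate", "confidence")


def read_psm_table(
    path: Union[str, Path],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> tuple[list[PSMRecord], int]:
    """Read a PSM TSV, dropping rows below the confidence threshold.

    Returns the retained records and the dropped-row count (also logged).
    """
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise FormatError(f"{path}: empty file")
        header = header_line.split("\t")
        missing = [c for c in _PSM_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column {missing[0]!r}")
        idx = {c: header.index(c) for c in _PSM_COLUMNS}
        records: list[PSMRecord] = []
        dropped = 0
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
            try:
                conf = float(fields[idx["confidence"]])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric confidence "
                    f"{fields[idx['confidence']]!r}"
                ) from None
            try:
                rep = int(fields[idx["replicate"]])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer replicate "
                    f"{fields[idx['replicate']]!r}"
                ) from None
            if conf < min_confidence:
                dropped += 1
                continue
            records.append(
                PSMRecord(fields[idx["peptide"]], fields[idx["sample"]], rep, conf)
            )
    if not records and dropped == 0:
        log.warning("%s: header-only PSM table", path)
    if dropped:
        log.info("%s: %d PSMs dropped below confidence %g", path, dropped, min_confidence)
    return records, dropped


def write_psm_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a PSM table (columns peptide, sample, replicate, confidence)."""
    missing = [c for c in _PSM_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"PSM table missing column {missing[0]!r}")
    table[list(_PSM_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# category annotation
# ---------------------------------------------------------------------------

def read_annotation(path: Union[str, Path]) -> dict[str, str]:
    """Read accession -> functional category (closed 22-name vocabulary)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("accession", "category"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out: dict[str, str] = {}
    for i, row in df.iterrows():
        if row["category"] not in FUNCTIONAL_CATEGORIES:
            raise FormatError(
                f"{path}: line {i + 2}: unknown category {row['category']!r}"
            )
        out[row["accession"]] = row["category"]
    return out


def write_annotation(annotation: Mapping[str, str], path: Union[str, Path]) -> None:
    pd.DataFrame(
        sorted(annotation.items()), columns=["accession", "category"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# immunogold scenes (JSON)
# ---------------------------------------------------------------------------

def write_gold_scene(scene: GoldScene, path: Union[str, Path]) -> None:
    doc = {
        "scene_id": scene.scene_id,
        "animal": scene.animal,
        "dilution": scene.dilution,
        "is_control": scene.is_control,
        "coordinate_convention": COORD_CONVENTION,
        "structures": [
            {
                "compartment": s.compartment,
                "section_kind": s.section_kind,
                "closed": s.closed,
                "points": [[x, y] for x, y in s.points],
            }
            for s in scene.structures
        ],
        "particles": [
            {"x": p.x, "y": p.y, **({"truth": p.truth} if p.truth else {})}
            for p in scene.particles
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_gold_scene(path: Union[str, Path]) -> GoldScene:
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: malformed JSON at line {exc.lineno}") from None
    for key in ("scene_id", "animal", "dilution", "is_control", "structures", "particles"):
        if key not in doc:
            raise FormatError(f"{path}: missing key {key!r}")
    structures = []
    for i, s in enumerate(doc["structures"]):
        if "compartment" not in s:
            raise FormatError(f"{path}: polyline {i} missing compartment label")
        if "section_kind" not in s:
            raise FormatError(f"{path}: polyline {i} missing section_kind label")
        structures.append(
            Structure(
                compartment=s["compartment"],
                section_kind=s["section_kind"],
                points=tuple((float(x), float(y)) for x, y in s["points"]),
                closed=bool(s.get("closed", False)),
            )
        )
    particles = [
        Particle(float(p["x"]), float(p["y"]), p.get("truth")) for p in doc["particles"]
    ]
    return GoldScene(
        scene_id=doc["scene_id"],
        animal=doc["animal"],
        dilution=doc["dilution"],
        is_control=bool(doc["is_control"]),
        structures=structures,
        particles=particles,
    )


# ---------------------------------------------------------------------------
# matrices, generic TSV, CDT/GTR
# ---------------------------------------------------------------------------

def order_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Stable row order: descending overall abundance, then accession."""
    order = sorted(matrix.index, key=lambda a: (-matrix.loc[a].sum(), a))
    return matrix.loc[order]


def write_quant_matrix(matrix: pd.DataFrame, path: Union[str, Path]) -> None:
    out = matrix.copy()
    out.index.name = "accession"
    out.to_csv(path, sep="\t")


def read_quant_matrix(path: Union[str, Path]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col="accession")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    return df


def write_tsv(frame: pd.DataFrame, path: Union[str, Path], index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def write_cdt_gtr(
    matrix: pd.DataFrame,
    result: ClusterResult,
    base_path: Union[str, Path],
) -> tuple[Path, Path]:
    """Write ``<base>.cdt`` and ``<base>.gtr`` for tree viewers.

    The CDT lists rows in dendrogram leaf order with GENE ids referring to
    input row order; the GTR encodes the merge tree with similarity
    = 1 - merge height.
    """
    base = Path(base_path)
    cdt_path = base.with_suffix(".cdt")
    gtr_path = base.with_suffix(".gtr")
    gid = {name: f"GENE{i}X" for i, name in enumerate(result.row_names)}

    with open(cdt_path, "w", encoding="utf-8") as fh:
        cols = "\t".join(str(c) for c in matrix.columns)
        fh.write(f"GID\tUNIQID\tNAME\tGWEIGHT\t{cols}\n")
        for name in result.leaf_order:
            vals = "\t".join(repr(float(v)) for v in matrix.loc[name])
            fh.write(f"{gid[name]}\t{name}\t{name}\t1\t{vals}\n")

    n = len(result.row_names)
    with open(gtr_path, "w", encoding="utf-8") as fh:
        for k, (a, b, height, _) in enumerate(result.linkage_matrix):
            left = gid[result.row_names[int(a)]] if a < n else f"NODE{int(a) - n}X"
            right = gid[result.row_names[int(b)]] if b < n else f"NODE{int(b) - n}X"
            fh.write(f"NODE{k}X\t{left}\t{right}\t{repr(1.0 - float(height))}\n")
    return cdt_path, gtr_path
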
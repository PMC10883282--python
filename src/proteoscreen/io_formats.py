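"""Readers and writers for every table the pipeline touches.

All matrix/annotation tables are TSV (tab separated, UTF-8, '.' decimal);
drug-screen plates are long-format CSV. Writers emit a sidecar schema line
as a leading ``#`` comment so files are self-describing; readers skip it.

Conventions shared with search-engine output tables:

* intensity cells holding 0 or nothing are *missing*, not observed zeros —
  search engines write 0 for non-detection, and half-minimum imputation
  must not treat those as measurements;
* decoy hits carry a ``+`` in the Reverse column, contaminants in the
  Potential contaminant column;
* phosphorylation sites are identified as ``GENE_<residue><position>``
  (e.g. ``RRM2_T33``), 1-based protein coordinates, for joinability with
  annotation files.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import LINEAR, AbundanceMatrix

logger = logging.getLogger("proteoscreen")

PROTEOME_INTENSITY_PREFIX = "iBAQ "
PHOSPHO_INTENSITY_PREFIX = "Intensity "

WELL_ROLES = ("sample", "positive_control", "negative_control")


class SchemaError(ValueError):
    """A table is missing a mandatory column or violates an invariant."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass
class ProteinRecord:
    protein_group_id: str
    gene_name: str
    intensities: dict[str, float]  # sample -> linear intensity; missing keys absent
    is_reverse: bool = False
    is_contaminant: bool = False


@dataclass
class PhosphoSiteRecord:
    site_id: str  # "GENE_T33"
    protein_group_id: str
    gene_name: str
    residue: str  # S, T or Y
    position: int  # 1-based
    localization_probability: float
    intensities: dict[str, float]
    is_reverse: bool = False
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise SchemaError(f"residue must be S/T/Y, got {self.residue!r}")
        if not (0.0 <= self.localization_probability <= 1.0):
            raise SchemaError(
                "localization probability outside [0, 1]: "
                f"{self.localization_probability}"
            )
        if self.position < 1:
            raise SchemaError(f"position must be 1-based, got {self.position}")


@dataclass
class ScreenWellRecord:
    drug: str
    cell_line: str
    dose: float  # µM; 0 for vehicle/control wells
    replicate: int
    signal: float  # luminescence-like, arbitrary units
    well_role: str = "sample"

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise SchemaError(f"negative dose {self.dose} for {self.drug}")
        if self.replicate < 1:
            raise SchemaError(f"replicate must be >= 1, got {self.replicate}")
        if self.well_role not in WELL_ROLES:
            raise SchemaError(f"unknown well_role {self.well_role!r}")


@dataclass
class AnnotationSet:
    """Kinase, activation-loop, substrate and periodic-cluster annotations."""

    kinase_ids: set[str] = field(default_factory=set)
    activation_loop_sites: dict[str, set[str]] = field(default_factory=dict)
    substrate_sites: dict[str, set[str]] = field(default_factory=dict)
    druggable_kinases: set[str] = field(default_factory=set)
    periodic_clusters: dict[int, set[str]] = field(default_factory=dict)

    def loop_sites(self, kinase: str) -> set[str]:
        return self.activation_loop_sites.get(kinase, set())

    def substrates(self, kinase: str) -> set[str]:
        return self.substrate_sites.get(kinase, set())


def make_site_id(gene: str, residue: str, position: int) -> str:
    return f"{gene}_{residue}{position}"


# ---------------------------------------------------------------------------
# low-level TSV helpers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)

def _require(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")


def _parse_intensity(cell: str) -> float | None:
    """Empty cells and zeros are missing; anything else must parse."""
    if cell.strip() == "":
        return None
    value = float(cell)
    if value < 0:
        raise SchemaError(f"negative intensity {value}")
    return None if value == 0 else value


def _intensity_columns(df: pd.DataFrame, prefix: str, path: str | Path) -> list[str]:
    cols = [c for c in df.columns if c.startswith(prefix)]
    if not cols:
        raise SchemaError(f"{path}: no intensity columns with prefix {prefix!r}")
    return cols


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_protein_groups(
    path: str | Path, intensity_prefix: str = PROTEOME_INTENSITY_PREFIX
) -> list[ProteinRecord]:
    """Read a protein-groups table ("proteinGroups.txt" dialect).

    Intensity columns are discovered by ``intensity_prefix``; the sample name
    is the column name with the prefix stripped.
    """
    df = _read_table(path, sep="\t")
    _require(df, ["Protein IDs", "Gene names"], path)
    cols = _intensity_columns(df, intensity_prefix, path)

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = row["Protein IDs"]
        if pid in seen:
            raise SchemaError(f"{path}: duplicate protein group id {pid!r}")
        seen.add(pid)
        intensities = {}
        for col in cols:
            v = _parse_intensity(row[col])
            if v is not None:
                intensities[col[len(intensity_prefix):]] = v
        records.append(
            ProteinRecord(
                protein_group_id=pid,
                gene_name=row["Gene names"],
                intensities=intensities,
                is_reverse=pid.startswith("REV__") or row.get("Reverse", "") == "+",
                is_contaminant=pid.startswith("CON__")
                or row.get("Potential contaminant", "") == "+",
            )
        )
    return records


def read_phospho_sites(
    path: str | Path, intensity_prefix: str = PHOSPHO_INTENSITY_PREFIX
) -> list[PhosphoSiteRecord]:
    """Read a phosphorylation-site table ("Phospho (STY)Sites.txt" dialect).

    The site id is synthesised as ``GENE_<residue><position>``. Sites are not
    filtered on localisation probability; the probability is carried through
    for downstream display.
    """
    df = _read_table(path, sep="\t")
    _require(
        df,
        ["Protein", "Gene names", "Amino acid", "Position", "Localization prob"],
        path,
    )
    cols = _intensity_columns(df, intensity_prefix, path)

    records: list[PhosphoSiteRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        gene = row["Gene names"]
        site_id = make_site_id(gene, row["Amino acid"], int(row["Position"]))
        if site_id in seen:
            raise SchemaError(f"{path}: duplicate site id {site_id!r}")
        seen.add(site_id)
        intensities = {}
        for col in cols:
            v = _parse_intensity(row[col])
            if v is not None:
                intensities[col[len(intensity_prefix):]] = v
        records.append(
            PhosphoSiteRecord(
                site_id=site_id,
                protein_group_id=row["Protein"],
                gene_name=gene,
                residue=row["Amino acid"],
                position=int(row["Position"]),
                localization_probability=float(row["Localization prob"]),
                intensities=intensities,
                is_reverse=row["Protein"].startswith("REV__")
                or row.get("Reverse", "") == "+",
                is_contaminant=row["Protein"].startswith("CON__")
                or row.get("Potential contaminant", "") == "+",
            )
        )
    return records


def read_drug_screen(path: str | Path) -> list[ScreenWellRecord]:
    """Read a long-format drug-screen CSV (one row per well)."""
    df = _read_table(path, sep=",")
    _require(df, ["drug", "cell_line", "dose_um", "replicate", "signal"], path)
    records = []
    for _, row in df.iterrows():
        records.append(
            ScreenWellRecord(
                drug=row["drug"],
                cell_line=row["cell_line"],
                dose=float(row["dose_um"]),
                replicate=int(row["replicate"]),
                signal=float(row["signal"]),
                well_role=row.get("well_role", "sample") or "sample",
            )
        )
    return records


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    df = _read_table(path, sep="\t")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expected a two-column (key, member) TSV")
    key_col, member_col = df.columns[:2]
    return [(str(k), str(m)) for k, m in zip(df[key_col], df[member_col])]


def read_annotations(
    kinase_path: str | Path,
    loop_path: str | Path,
    substrate_path: str | Path,
    cluster_path: str | Path,
    druggable_path: str | Path | None = None,
) -> AnnotationSet:
    """Assemble the annotation set from two-column (key, member) TSVs.

    * kinase file: (``kinase``, kinase gene id) — defines the kinase universe;
    * loop file: (kinase, activation-loop site id);
    * substrate file: (kinase, substrate site id);
    * cluster file: (cluster label 1..5, protein id) — memberships must be
      disjoint;
    * optional druggable file: (``druggable``, kinase id).
    """
    ann = AnnotationSet()
    for _, member in _read_pairs(kinase_path):
        ann.kinase_ids.add(member)
    for kinase, site in _read_pairs(loop_path):
        ann.activation_loop_sites.setdefault(kinase, set()).add(site)
    for kinase, site in _read_pairs(substrate_path):
        ann.substrate_sites.setdefault(kinase, set()).add(site)
    assigned: dict[str, int] = {}
    for label, protein in _read_pairs(cluster_path):
        lab = int(label)
        if not 1 <= lab <= 5:
            raise SchemaError(f"{cluster_path}: cluster label {lab} outside 1..5")
        if protein in assigned and assigned[protein] != lab:
            raise SchemaError(
                f"{cluster_path}: protein {protein!r} assigned to clusters "
                f"{assigned[protein]} and {lab}"
            )
        assigned[protein] = lab
        ann.periodic_clusters.setdefault(lab, set()).add(protein)
    if druggable_path is not None:
        for _, kinase in _read_pairs(druggable_path):
            ann.druggable_kinases.add(kinase)
    return ann


# ---------------------------------------------------------------------------
# writers (12-significant-digit round trip)
# ---------------------------------------------------------------------------

_FMT = "%.12g"


def _fmt(x: float | None) -> str:
    return "" if x is None else _FMT % x


def write_protein_groups(
    records: list[ProteinRecord],
    path: str | Path,
    intensity_prefix: str = PROTEOME_INTENSITY_PREFIX,
) -> None:
    samples = sorted({s for r in records for s in r.intensities})
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# schema: proteinGroups v1; 0/empty = missing\n")
        header = ["Protein IDs", "Gene names", "Reverse", "Potential contaminant"]
        header += [intensity_prefix + s for s in samples]
        w = csv.writer(fh, delimiter="\t")
        w.writerow(header)
        for r in records:
            row = [
                r.protein_group_id,
                r.gene_name,
                "+" if r.is_reverse else "",
                "+" if r.is_contaminant else "",
            ]
            row += [_fmt(r.intensities.get(s)) for s in samples]
            w.writerow(row)


def write_phospho_sites(
    records: list[PhosphoSiteRecord],
    path: str | Path,
    intensity_prefix: str = PHOSPHO_INTENSITY_PREFIX,
) -> None:
    samples = sorted({s for r in records for s in r.intensities})
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# schema: phosphoSites v1; 0/empty = missing\n")
        header = [
            "Protein",
            "Gene names",
            "Amino acid",
            "Position",
            "Localization prob",
            "Reverse",
            "Potential contaminant",
        ]
        header += [intensity_prefix + s for s in samples]
        w = csv.writer(fh, delimiter="\t")
        w.writerow(header)
        for r in records:
            row = [
                r.protein_group_id,
                r.gene_name,
                r.residue,
                str(r.position),
                _FMT % r.localization_probability,
                "+" if r.is_reverse else "",
                "+" if r.is_contaminant else "",
            ]
            row += [_fmt(r.intensities.get(s)) for s in samples]
            w.writerow(row)


def write_drug_screen(records: list[ScreenWellRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# schema: drugScreen v1; dose_um in micromolar\n")
        w = csv.writer(fh)
        w.writerow(["drug", "cell_line", "dose_um", "replicate", "signal", "well_role"])
        for r in records:
            w.writerow(
                [r.drug, r.cell_line, _FMT % r.dose, r.replicate, _FMT % r.signal,
                 r.well_role]
            )


def write_pairs(pairs: list[tuple[str, str]], path: str | Path,
                key_name: str = "key", member_name: str = "member") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schema: pairs v1 ({key_name}, {member_name})\n")
        w = csv.writer(fh, delimiter="\t")
        w.writerow([key_name, member_name])
        for k, m in pairs:
            w.writerow([k, m])


def write_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# schema: abundanceMatrix v1; scale={matrix.scale_tag}\n")
        matrix.values.to_csv(fh, sep="\t", float_format=_FMT, index_label="feature_id")


def read_matrix(path: str | Path, scale_tag: str | None = None) -> AbundanceMatrix:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            if scale_tag is None and "scale=" in first:
                scale_tag = first.rsplit("scale=", 1)[1].strip()
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col="feature_id")
    return AbundanceMatrix(df, scale_tag or LINEAR)


# ---------------------------------------------------------------------------
# record list -> matrix
# ---------------------------------------------------------------------------


def records_to_matrix(
    records: list[ProteinRecord] | list[PhosphoSiteRecord],
) -> tuple[AbundanceMatrix, pd.Series]:
    """Stack record intensities into a linear-scale matrix.

    Returns the matrix plus a boolean flag Series (reverse OR contaminant)
    aligned to its feature index, ready for
    :func:`~proteoscreen.preprocessing.filter_decoys_contaminants`.
    """
    ids = [
        r.site_id if isinstance(r, PhosphoSiteRecord) else r.protein_group_id
        for r in records
    ]
    samples = sorted({s for r in records for s in r.intensities})
    data = np.full((len(records), len(samples)), np.nan)
    for i, r in enumerate(records):
        for j, s in enumerate(samples):
            if s in r.intensities:
                data[i, j] = r.intensities[s]
    matrix = AbundanceMatrix(pd.DataFrame(data, index=ids, columns=samples), LINEAR)
    flags = pd.Series(
        [r.is_reverse or r.is_contaminant for r in records], index=ids, dtype=bool
    )
    return matrix, flags
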
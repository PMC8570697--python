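"""Domain containers and TSV readers/writers shared by every stage.

All interchange is plain tab-separated text: a gene-by-sample count table
with a header row, a sample sheet, and an OrthoFinder-style
``Orthogroups.tsv``.  Containers are thin dataclasses around pandas/numpy
objects that validate their invariants on construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

#: the four Caenorhabditis species of the study, in phylogeny-figure order
DEFAULT_SPECIES = ("C. elegans", "C. briggsae", "C. kamaaina", "C. tropicalis")

#: parental stress contrasts profiled in F1/F3 offspring
DEFAULT_STRESSES = ("pathogen", "osmotic")

GENERATIONS = ("F1", "F3")


@dataclass
class CountMatrix:
    """Raw integer counts, genes x samples, for one species."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    species_tag: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.counts = np.asarray(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return CountMatrix(list(genes), self.sample_ids, self.counts[rows], self.species_tag)

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return CountMatrix(self.gene_ids, list(samples), self.counts[:, cols], self.species_tag)


@dataclass
class SampleSheet:
    """Per-sample annotations: species, generation, parental condition, replicate."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "species", "generation", "parental_condition", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if self.frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        bad_gen = set(self.frame["generation"]) - set(GENERATIONS)
        if bad_gen:
            raise ValidationError(f"unknown generation labels: {sorted(bad_gen)}")
        if (self.frame["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate numbers must be positive")
        self.frame = self.frame.reset_index(drop=True)

    def samples_for(self, species: str, generation: str, condition: str) -> list[str]:
        f = self.frame
        sel = (
            (f["species"] == species)
            & (f["generation"] == generation)
            & (f["parental_condition"] == condition)
        )
        return list(f.loc[sel, "sample_id"])

    def conditions(self, species: str, generation: str = "F1") -> list[str]:
        f = self.frame
        sel = (f["species"] == species) & (f["generation"] == generation)
        return sorted(f.loc[sel, "parental_condition"].unique())


@dataclass
class OrthogroupTable:
    """Orthogroup membership per species (OrthoFinder ``Orthogroups.tsv`` content)."""

    entries: dict[str, dict[str, list[str]]]  # og_id -> species -> gene ids
    species: list[str]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for og_id, members in self.entries.items():
            for sp, genes in members.items():
                if sp not in self.species:
                    raise ValidationError(f"orthogroup {og_id} names unknown species {sp!r}")
                for g in genes:
                    key = (sp, g)
                    if key in seen:
                        raise ValidationError(
                            f"gene {g!r} ({sp}) appears in orthogroups "
                            f"{seen[key]} and {og_id}"
                        )
                    seen[key] = og_id

    def copy_numbers(self, og_id: str) -> dict[str, int]:
        return {sp: len(self.entries[og_id].get(sp, [])) for sp in self.species}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AnalysisConfig:
    """Thresholds, species/stress roster and seed driving a pipeline run."""

    species: tuple[str, ...] = DEFAULT_SPECIES
    stresses: tuple[str, ...] = DEFAULT_STRESSES
    fold_change_threshold: float = 2.0
    padj_threshold: float = 0.01
    pseudocount: float = 1.0
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.fold_change_threshold <= 1:
            raise ConfigurationError("fold_change_threshold must exceed 1")
        if not (0 < self.padj_threshold < 1):
            raise ConfigurationError("padj_threshold must lie in (0, 1)")
        if self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be positive")
        self.species = tuple(self.species)
        self.stresses = tuple(self.stresses)

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dc_fields(cls)}


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path: str | Path, species_tag: str = "") -> CountMatrix:
    """Read a gene-by-sample TSV (header row; first column = gene id)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error surface
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    values = np.empty(frame.shape, dtype=np.int64)
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col]):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {raw!r} at gene "
                    f"{frame.index[i]!r}, sample {col!r}"
                ) from None
            if v < 0:
                raise FormatError(
                    f"{path}: negative count {v} at gene {frame.index[i]!r}, "
                    f"sample {col!r}"
                )
            values[i, j] = v
    return CountMatrix(list(frame.index), list(frame.columns), values, species_tag)


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "species": str})
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_orthogroups(path: str | Path, species: Sequence[str]) -> OrthogroupTable:
    """Parse the OrthoFinder ``Orthogroups.tsv`` dialect.

    First column is the orthogroup id; one column per species; members
    within a cell are separated by ``", "``; an empty cell means the
    species has no member in that group.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [sp for sp in species if sp not in frame.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing species columns {missing}")
    og_col = frame.columns[0]
    entries: dict[str, dict[str, list[str]]] = {}
    for _, row in frame.iterrows():
        og_id = row[og_col]
        members = {}
        for sp in species:
            cell = row[sp].strip()
            members[sp] = [g for g in (x.strip() for x in cell.split(",")) if g] if cell else []
        entries[og_id] = members
    return OrthogroupTable(entries, list(species))


def write_orthogroups(ogs: OrthogroupTable, path: str | Path) -> None:
    rows = []
    for og_id in ogs.entries:
        row = {"Orthogroup": og_id}
        for sp in ogs.species:
            row[sp] = ", ".join(ogs.entries[og_id].get(sp, []))
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *ogs.species]).to_csv(path, sep="\t", index=False)


def write_summary(results: Mapping[str, object], outdir: str | Path) -> dict[str, str]:
    """Write per-stage TSV tables plus one ``summary.json`` of headline counts.

    ``results`` maps a stage name either to a DataFrame (written as
    ``<stage>.tsv``) or to a scalar/mapping folded into the summary
    document.  Returns a manifest mapping stage name to file path.
    Output is deterministic for identical inputs (sorted keys, no
    timestamps).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {outdir}: {exc}") from exc
    manifest: dict[str, str] = {}
    summary: dict[str, object] = {}
    for name in sorted(results):
        value = results[name]
        if isinstance(value, pd.DataFrame):
            target = outdir / f"{name}.tsv"
            value.to_csv(target, sep="\t", index=False)
            manifest[name] = str(target)
            summary[f"{name}_rows"] = int(len(value))
        else:
            summary[name] = value
    target = outdir / "summary.json"
    with open(target, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    manifest["summary"] = str(target)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
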
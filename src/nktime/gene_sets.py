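"""Gene-set collections and the tabular formats shared by every pipeline stage.

Gene sets travel as GMT (one set per line: name, description, genes...);
expression as a genes x samples TSV; clinical outcomes as a TSV with
``sample``, ``time`` (days) and ``event`` (0/1) columns.  Readers validate
and reject malformed input rather than coerce it: expression values must be
numeric and non-negative, with no missing cells.

The fixture universe generator emits synthetic gene identifiers carved into
the named sets the analysis expects — an NK-specific set (157 genes), the
ligands of NK-activating receptors (40), ITAM-signaling genes, a tumor
immune panel (1294), per-cell-type TIL marker sets and two pathway sets
(NK cell-mediated cytotoxicity and Wnt) — all pairwise disjoint so planted
signals stay attributable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "GeneSetError",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "make_fixture_universe",
    "TIL_CELL_TYPES",
    "FIXTURE_SET_SIZES",
]


class GeneSetError(ValueError):
    """Malformed gene-set input."""


@dataclasses.dataclass
class GeneSetCollection:
    """A named collection of gene sets (ordered, duplicate-free)."""

    name: str
    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for set_name, genes in self.sets.items():
            if not set_name:
                raise GeneSetError("empty set name")
            if len(set(genes)) != len(genes):
                raise GeneSetError(f"duplicate genes within set {set_name!r}")
            if any((not isinstance(g, str)) or g == "" for g in genes):
                raise GeneSetError(f"empty or non-string gene id in set {set_name!r}")

    def __getitem__(self, set_name: str) -> list[str]:
        return self.sets[set_name]

    def __contains__(self, set_name: str) -> bool:
        return set_name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, prefix: str) -> "GeneSetCollection":
        """Collection restricted to sets whose name starts with ``prefix``."""
        picked = {k: list(v) for k, v in self.sets.items() if k.startswith(prefix)}
        return GeneSetCollection(name=f"{self.name}:{prefix}", sets=picked)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Duplicate genes within a line are removed keeping the first occurrence.
    A duplicated set name or a line with fewer than three fields is an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GeneSetError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise GeneSetError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g != ""]
            if not genes:
                raise GeneSetError(f"{path.name}:{lineno}: set {name!r} has no genes")
            sets[name] = list(dict.fromkeys(genes))
    return GeneSetCollection(name=path.stem, sets=sets)


def write_gmt(
    collection: GeneSetCollection,
    path: str | Path,
    descriptions: dict[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for set_name, genes in collection.sets.items():
            desc = descriptions.get(set_name, "na")
            fh.write("\t".join([set_name, desc, *genes]) + "\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV into a float DataFrame.

    First column is the gene id, header row the sample ids.  Non-numeric or
    missing cells are errors reported with their (gene, sample) coordinates;
    negative values are rejected.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path.name}: duplicate gene ids {dupes[:5]}")
    if raw.columns.has_duplicates:
        raise ValueError(f"{path.name}: duplicate sample ids")
    values = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = values.isna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        cell = raw.iat[gi, si]
        what = "missing" if pd.isna(cell) else f"non-numeric value {cell!r}"
        raise ValueError(
            f"{path.name}: {what} at gene {raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    if (values.to_numpy() < 0).any():
        gi, si = np.argwhere(values.to_numpy() < 0)[0]
        raise ValueError(
            f"{path.name}: negative expression at gene {values.index[gi]!r}, "
            f"sample {values.columns[si]!r}"
        )
    values.index.name = "gene"
    return values.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", lineterminator="\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV (sample, time, event) indexed by sample."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    df = df.set_index("sample")
    if df.index.has_duplicates:
        raise ValueError(f"{path.name}: duplicate sample ids")
    if (df["time"] < 0).any():
        raise ValueError(f"{path.name}: negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path.name}: event column must be 0/1")
    return df[["time", "event"]].astype({"time": float, "event": int})


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample", lineterminator="\n")


# Printed sizes of the study's named sets: 157 NK-specific genes, ~40
# ligands of NK-activating receptors, a 1294-gene tumor immune panel.
FIXTURE_SET_SIZES: dict[str, int] = {
    "nk_specific": 157,
    "ligand": 40,
    "itam": 30,
    "immune_panel": 1294,
    "pathway_nk_cytotoxicity": 60,
    "pathway_wnt": 60,
}

TIL_CELL_TYPES: tuple[str, ...] = (
    "NK",
    "NKT",
    "gdT",
    "CD8T",
    "CD4T",
    "cDC103",
    "Bcell",
    "MDSC",
)
_MARKERS_PER_CELL_TYPE = 20


def make_fixture_universe(
    n_genes: int = 6000, seed: int = 0
) -> tuple[GeneSetCollection, list[str]]:
    """Deterministically carve ``n_genes`` synthetic gene ids into fixture sets.

    Returns the collection plus the full gene universe.  Sets are disjoint by
    construction; TIL marker sets are named ``til_<cell type>``.
    """
    minimum = sum(FIXTURE_SET_SIZES.values()) + _MARKERS_PER_CELL_TYPE * len(
        TIL_CELL_TYPES
    )
    if n_genes < minimum:
        raise ValueError(
            f"n_genes={n_genes} too small to host disjoint fixture sets; minimum {minimum}"
        )
    universe = [f"G{i:05d}" for i in range(n_genes)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_genes)
    sets: dict[str, list[str]] = {}
    cursor = 0
    for set_name, size in FIXTURE_SET_SIZES.items():
        sets[set_name] = [universe[j] for j in order[cursor : cursor + size]]
        cursor += size
    for cell_type in TIL_CELL_TYPES:
        sets[f"til_{cell_type}"] = [
            universe[j] for j in order[cursor : cursor + _MARKERS_PER_CELL_TYPE]
        ]
        cursor += _MARKERS_PER_CELL_TYPE
    return GeneSetCollection(name="fixture", sets=sets), universe
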
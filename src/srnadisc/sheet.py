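"""The 3-sheet experiment workbook: parsing, validation, writing.

The workbook is the structured interface between the wet lab and the
pipeline. Three fixed sheets:

* ``Project`` — key/value rows: title, comments, species, adapter, alpha,
  quality_cutoff, min_length (processing settings live here);
* ``Samples`` — one row per sample: ``sample``, ``file``, then up to five
  grouping variable columns with arbitrary levels;
* ``Contrasts`` — one row per contrast: ``name``, ``variable``,
  ``group_a``, ``group_b``, ``blocking`` (optional). A contrast side may
  pool several levels of the variable joined by ``+`` ("A+B vs C").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .de import DesignSpec

MAX_GROUP_VARIABLES = 5
SHEET_NAMES = ("Project", "Samples", "Contrasts")


class SheetError(ValueError):
    """Workbook violates the experiment sheet schema."""


@dataclass
class ProjectInfo:
    title: str = ""
    comments: str = ""
    species: str = ""
    adapter: str = ""
    alpha: float = 0.05
    quality_cutoff: int = 20
    min_length: int = 17


@dataclass
class ContrastSpec:
    """One requested comparison: log2(side A / side B) on ``variable``."""

    name: str
    variable: str
    levels_a: tuple[str, ...]
    levels_b: tuple[str, ...]
    blocking: Optional[str] = None

    @staticmethod
    def parse_side(text: str) -> tuple[str, ...]:
        return tuple(part.strip() for part in str(text).split("+") if part.strip())


@dataclass
class ExperimentSheet:
    """Validated content of the metadata workbook."""

    project: ProjectInfo
    samples: pd.DataFrame  # indexed by sample id; 'file' + grouping columns
    contrasts: list[ContrastSpec]

    @property
    def group_variables(self) -> list[str]:
        return [c for c in self.samples.columns if c != "file"]

    def design_for(self, contrast: ContrastSpec) -> DesignSpec:
        """Resolve a contrast to the design the DE engine consumes."""
        groups = self.samples[contrast.variable].astype(str).to_dict()
        blocking = (
            self.samples[contrast.blocking].astype(str).to_dict()
            if contrast.blocking else None
        )
        return DesignSpec(
            samples=list(self.samples.index),
            group=groups,
            contrast=(contrast.levels_a, contrast.levels_b),
            blocking=blocking,
        )


def _validate(sheet: ExperimentSheet, base_dir: Optional[Path],
              check_files: bool) -> None:
    samples = sheet.samples
    if samples.index.duplicated().any():
        dups = sorted(set(samples.index[samples.index.duplicated()]))
        raise SheetError(f"duplicate sample ids: {dups}")
    gvars = sheet.group_variables
    if len(gvars) > MAX_GROUP_VARIABLES:
        raise SheetError(
            f"{len(gvars)} grouping variables exceed the limit of "
            f"{MAX_GROUP_VARIABLES}: {gvars}"
        )
    for c in sheet.contrasts:
        if c.variable not in gvars:
            raise SheetError(
                f"contrast {c.name!r} references unknown variable {c.variable!r}; "
                f"available: {gvars}"
            )
        levels = set(samples[c.variable].astype(str))
        for side, named in (("A", c.levels_a), ("B", c.levels_b)):
            unknown = [lv for lv in named if lv not in levels]
            if unknown:
                raise SheetError(
                    f"contrast {c.name!r} side {side} names unknown level(s) "
                    f"{unknown} of variable {c.variable!r}; levels: {sorted(levels)}"
                )
        if c.blocking and c.blocking not in gvars:
            raise SheetError(
                f"contrast {c.name!r} blocking variable {c.blocking!r} unknown; "
                f"available: {gvars}"
            )
    if check_files and base_dir is not None:
        missing = [
            s for s, f in samples["file"].items()
            if not (base_dir / str(f)).exists()
        ]
        if missing:
            raise SheetError(f"sample file(s) not found for: {missing}")


def parse_sheet(path: str | Path, check_files: bool = True) -> ExperimentSheet:
    """Parse and validate the 3-sheet workbook (xlsx).

    Sample file paths are resolved relative to the workbook's directory;
    existence is checked unless ``check_files=False``.
    """
    path = Path(path)
    book = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    missing = [s for s in SHEET_NAMES if s not in book]
    if missing:
        raise SheetError(f"workbook lacks required sheet(s): {missing}")

    proj_df = book["Project"]
    kv = {
        str(k).strip(): v
        for k, v in zip(proj_df.iloc[:, 0], proj_df.iloc[:, 1])
        if pd.notna(k)
    }
    def _get(key, default, cast):
        v = kv.get(key, default)
        return default if pd.isna(v) or v == "" else cast(v)
    project = ProjectInfo(
        title=_get("title", "", str),
        comments=_get("comments", "", str),
        species=_get("species", "", str),
        adapter=_get("adapter", "", str),
        alpha=_get("alpha", 0.05, float),
        quality_cutoff=_get("quality_cutoff", 20, int),
        min_length=_get("min_length", 17, int),
    )

    samples = book["Samples"]
    if "sample" not in samples.columns or "file" not in samples.columns:
        raise SheetError("Samples sheet requires 'sample' and 'file' columns")
    samples = samples.set_index(samples["sample"].astype(str)).drop(columns=["sample"])
    samples.index.name = "sample"

    contrasts = []
    cdf = book["Contrasts"]
    required = {"name", "variable", "group_a", "group_b"}
    if len(cdf) and not required.issubset(cdf.columns):
        raise SheetError(
            f"Contrasts sheet requires columns {sorted(required)}"
        )
    for _, row in cdf.iterrows():
        if pd.isna(row.get("name")) or str(row.get("name")).strip() == "":
            continue
        blocking = row.get("blocking")
        blocking = None if pd.isna(blocking) or str(blocking).strip() == "" \
            else str(blocking).strip()
        contrasts.append(ContrastSpec(
            name=str(row["name"]).strip(),
            variable=str(row["variable"]).strip(),
            levels_a=ContrastSpec.parse_side(row["group_a"]),
            levels_b=ContrastSpec.parse_side(row["group_b"]),
            blocking=blocking,
        ))

    sheet = ExperimentSheet(project=project, samples=samples, contrasts=contrasts)
    _validate(sheet, path.parent, check_files)
    return sheet


def write_workbook(path: str | Path, project: dict, samples: pd.DataFrame,
                   contrasts: pd.DataFrame) -> Path:
    """Write a valid experiment workbook (used by the fixture generator)."""
    path = Path(path)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        pd.DataFrame(
            {"key": list(project.keys()), "value": list(project.values())}
        ).to_excel(writer, sheet_name="Project", index=False)
        samples.reset_index().to_excel(writer, sheet_name="Samples", index=False)
        cols = ["name", "variable", "group_a", "group_b", "blocking"]
        out = contrasts.reindex(columns=cols) if len(contrasts) else \
            pd.DataFrame(columns=cols)
        out.to_excel(writer, sheet_name="Contrasts", index=False)
    return path
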
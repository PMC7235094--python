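"""Laminar mapping, per-animal aggregation, the contingency chi-squared
and end-to-end pipeline orchestration.

Laminar region-of-interest (ROI) polygons follow the standard Rexed
scheme (I-II, III-IV, V, VI, VII, VIII, IX, X).  PSDs are assigned to a
lamina by point-in-polygon on their centroid; per-lamina summaries
mirror the mapping figures: whole-field intensity, PSD density, mean PSD
intensity, median PSD size and mean integrated intensity.  Aggregation
treats the animal as the statistical unit: hemisection means per animal,
then animal-level values into group mean ± SEM.  Only the Pearson
contingency chi-squared is implemented from formula; other inferential
tests operate on the animal-level tables through standard statistical
libraries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon

from .core import ChannelImage, ParameterError

__all__ = [
    "LAMINA_LABELS",
    "LaminaROI",
    "LaminaSummary",
    "ContingencyResult",
    "assign_lamina",
    "summarise_lamina",
    "aggregate_animals",
    "contingency_chi2",
    "rois_from_json",
    "rois_to_json",
    "run_pipeline",
]

LAMINA_LABELS = ("I-II", "III-IV", "V", "VI", "VII", "VIII", "IX", "X")


@dataclass
class LaminaROI:
    """A lamina polygon in physical µm coordinates."""

    label: str
    vertices_um: list  # [(x, y), ...]
    polygon: Polygon = field(init=False)

    def __post_init__(self) -> None:
        poly = Polygon(self.vertices_um)
        if not poly.is_valid or poly.area <= 0:
            raise ParameterError(
                f"ROI {self.label!r}: polygon must be simple with positive area"
            )
        self.polygon = poly

    @property
    def area_um2(self) -> float:
        return float(self.polygon.area)


@dataclass
class LaminaSummary:
    label: str
    n_psds: int
    area_um2: float
    psd_density: float  # per density_unit_um2
    density_unit_um2: float
    field_intensity: Optional[float]
    mean_psd_intensity: Optional[float]
    median_psd_size_um2: Optional[float]
    mean_integrated_intensity: Optional[float]


@dataclass
class ContingencyResult:
    table: np.ndarray
    chi2: float
    df: int
    p: float


def _validate_disjoint(rois: Sequence[LaminaROI]) -> None:
    for i in range(len(rois)):
        for j in range(i + 1, len(rois)):
            inter = rois[i].polygon.intersection(rois[j].polygon)
            if inter.area > 1e-9:
                raise ParameterError(
                    f"ROIs {rois[i].label!r} and {rois[j].label!r} overlap "
                    f"(area {inter.area:.3g} µm²)"
                )


def assign_lamina(
    centroids_um: np.ndarray,
    rois: Sequence[LaminaROI],
) -> list[Optional[str]]:
    """Label each centroid with the lamina ROI containing it.

    ROIs must be pairwise non-overlapping (validated; an overlapping
    pair raises with both labels named).  Containment uses the even-odd
    rule with boundary points counted as inside; points outside all ROIs
    get ``None``.
    """
    _validate_disjoint(rois)
    pts = np.asarray(centroids_um, dtype=float).reshape(-1, 2)
    labels: list[Optional[str]] = []
    for x, y in pts:
        point = Point(x, y)
        hit = None
        for roi in rois:
            if roi.polygon.covers(point):
                hit = roi.label
                break
        labels.append(hit)
    return labels


def summarise_lamina(
    psd_table: pd.DataFrame,
    roi: LaminaROI,
    raw: Optional[ChannelImage] = None,
    density_unit_um2: float = 100.0,
) -> LaminaSummary:
    """Per-lamina mapping metrics.

    ``psd_table`` needs columns ``x_um, y_um, area_um2, mean_intensity,
    integrated_intensity``; only PSDs whose centroid falls inside the
    ROI polygon contribute.  ``field_intensity`` is the mean raw pixel
    intensity over the ROI (``None`` when no raw image is supplied).
    Density is reported per ``density_unit_um2`` (default per 100 µm²).
    """
    inside = np.array([
        roi.polygon.covers(Point(x, y))
        for x, y in zip(psd_table["x_um"], psd_table["y_um"])
    ], dtype=bool) if len(psd_table) else np.zeros(0, dtype=bool)
    sub = psd_table[inside] if len(psd_table) else psd_table

    field_intensity = None
    if raw is not None:
        from skimage.draw import polygon2mask

        px = raw.pixel_size_um
        verts_px = [(y / px - 0.5, x / px - 0.5) for x, y in roi.vertices_um]
        mask = polygon2mask(raw.shape, verts_px)
        if mask.any():
            field_intensity = float(raw.pixels[mask].mean())

    n = int(len(sub))
    density = n / roi.area_um2 * density_unit_um2
    return LaminaSummary(
        label=roi.label,
        n_psds=n,
        area_um2=roi.area_um2,
        psd_density=density,
        density_unit_um2=density_unit_um2,
        field_intensity=field_intensity,
        mean_psd_intensity=float(sub["mean_intensity"].mean()) if n else None,
        median_psd_size_um2=float(sub["area_um2"].median()) if n else None,
        mean_integrated_intensity=(
            float(sub["integrated_intensity"].mean()) if n else None),
    )


def aggregate_animals(
    per_section: pd.DataFrame,
    design: pd.DataFrame,
    value_columns: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hemisection → animal → group aggregation.

    ``per_section`` holds one row per section with a ``section`` column
    plus numeric value columns; ``design`` maps every section to exactly
    one ``animal`` and ``group``.  Hemisection values are averaged per
    animal, then the animal-level values feed group mean ± SEM — the
    animal, not the section, is the statistical unit, so section order
    never affects the result.

    Returns ``(animal_table, group_table)``.
    """
    if not {"section", "animal", "group"}.issubset(design.columns):
        raise ParameterError("design needs columns: section, animal, group")
    if design["section"].duplicated().any():
        raise ParameterError("design maps a section more than once")
    missing = set(per_section["section"]) - set(design["section"])
    if missing:
        raise ParameterError(f"sections without design rows: {sorted(missing)}")

    merged = per_section.merge(design, on="section", how="left")
    if value_columns is None:
        value_columns = [
            c for c in per_section.columns
            if c != "section" and pd.api.types.is_numeric_dtype(per_section[c])
        ]
    animal = (
        merged.groupby(["group", "animal"], as_index=False)[list(value_columns)]
        .mean()
    )
    n_sections = merged.groupby(["group", "animal"]).size().rename("n_sections")
    animal = animal.merge(n_sections.reset_index(), on=["group", "animal"])

    def sem(x):
        x = np.asarray(x, dtype=float)
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    rows = []
    for grp, sub in animal.groupby("group"):
        row = {"group": grp, "n_animals": len(sub)}
        for col in value_columns:
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sem"] = sem(sub[col])
        rows.append(row)
    return animal, pd.DataFrame(rows)


def contingency_chi2(table) -> ContingencyResult:
    """Pearson chi-squared test of independence on an r×c count table.

    Expected counts come from the margins; the statistic is
    Σ (O − E)² / E with (r−1)(c−1) degrees of freedom and no continuity
    correction.  A zero row or column margin is a degenerate table.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ParameterError("table must be at least 2×2")
    if np.any(obs < 0):
        raise ParameterError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = obs.sum()
    if np.any(rows == 0) or np.any(cols == 0) or n == 0:
        raise ParameterError("degenerate table: zero margin")
    expected = np.outer(rows, cols) / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    return ContingencyResult(table=obs, chi2=chi2, df=df, p=p)


# ---------------------------------------------------------------------------
# ROI JSON interchange

def rois_from_json(path) -> list[LaminaROI]:
    with open(path) as fh:
        doc = json.load(fh)
    return [LaminaROI(label=e["label"],
                      vertices_um=[tuple(v) for v in e["vertices_um"]])
            for e in doc]


def rois_to_json(rois: Sequence[LaminaROI], path) -> None:
    doc = [{"label": r.label, "vertices_um": [list(v) for v in r.vertices_um]}
           for r in rois]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# orchestration

def run_pipeline(config, outdir=None, seed: Optional[int] = None) -> dict:
    """Run simulate → segment → hierarchy → colocalize on a config.

    ``config`` is a dict (or path to a YAML file) with optional keys:

    * ``scene``: keyword overrides for :class:`~nanosyn.synth.SceneParams`
    * ``seed``: base RNG seed (overridden by the ``seed`` argument)
    * ``analysis``: keyword overrides for
      :class:`~nanosyn.core.PipelineConfig`

    Every numeric constant used is echoed into the run record.  Outputs
    (PSD/NC tables as CSV, run record as JSON) are written to ``outdir``
    when given.  Returns the summary dict, including the measured and
    ground-truth tripartite and multi-NC fractions and detection
    precision/recall against the generated scene.
    """
    from . import pipeline as _pipeline

    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    config = dict(config)
    if seed is None:
        seed = int(config.get("seed", 0))
    return _pipeline.run_simulated_pipeline(
        scene_overrides=config.get("scene", {}),
        analysis_overrides=config.get("analysis", {}),
        seed=seed,
        outdir=outdir,
    )
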
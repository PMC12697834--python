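"""Synthetic DNA-origami-like SMLM data.

Generates labeled ROIs with the statistical structure of DNA-PAINT origami
data: each class is a layout of binding sites; each site emits a Poisson
number of localizations scattered with isotropic Gaussian error; uniform
background localizations model spurious detections; with some probability a
site fails to form ("misfolded" origami); the whole layout may land in a
random in-plane orientation, as origami do on a coverslip.

Defaults put the structures on the physical scale of real origami data:
13 nm site spacing, ~3 nm localization scatter, tens of localizations per
binding site. Photophysics (blinking kinetics, camera noise) and 3D are not
simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateSampleError, PreconditionError
from .io import LocalizationTable, write_locs

DEFAULT_SITE_SPACING = 13.0  # nm, between adjacent binding sites
DEFAULT_ROI_EXTENT = (200.0, 200.0)  # nm


@dataclass(frozen=True)
class TemplateLibrary:
    """Named binding-site layouts, one per class, in nm.

    Layout coordinates are centred inside ``roi_extent`` when sampled.
    """

    classes: list[tuple[str, np.ndarray]]
    roi_extent: tuple[float, float] = DEFAULT_ROI_EXTENT

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise PreconditionError("a template library needs >=2 classes")
        for name, layout in self.classes:
            layout = np.asarray(layout, float)
            if layout.ndim != 2 or layout.shape[1] != 2 or layout.shape[0] < 3:
                raise PreconditionError(f"layout {name!r} must be >=3 2D sites")
            span = layout.max(axis=0) - layout.min(axis=0)
            if span[0] > self.roi_extent[0] or span[1] > self.roi_extent[1]:
                raise PreconditionError(f"layout {name!r} exceeds the ROI extent")

    @property
    def class_names(self) -> list[str]:
        return [name for name, _ in self.classes]

    def layout(self, name: str) -> np.ndarray:
        for cname, sites in self.classes:
            if cname == name:
                return np.asarray(sites, float)
        raise KeyError(name)

    def subset(self, names: list[str]) -> "TemplateLibrary":
        return TemplateLibrary(
            [(n, self.layout(n)) for n in names], roi_extent=self.roi_extent
        )


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generative model; ``seed`` fully determines the output."""

    locs_per_site_mean: float = 30.0
    site_sigma: float = 3.0  # nm
    background_rate: float = 10.0  # expected background locs per ROI
    misfold_prob: float = 0.05  # independent per-site dropout
    rotation: bool = True  # random in-plane orientation per ROI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.locs_per_site_mean < 0 or self.background_rate < 0 or self.site_sigma < 0:
            raise PreconditionError("rates and sigma must be >= 0")
        if not (0.0 <= self.misfold_prob < 1.0):
            raise PreconditionError("misfold_prob must be in [0, 1)")


def _site_grid(rows: int, cols: int, spacing: float) -> np.ndarray:
    xx, yy = np.meshgrid(np.arange(cols) * spacing, np.arange(rows) * spacing)
    return np.column_stack([xx.ravel(), yy.ravel()]).astype(float)


def make_default_templates(spacing: float = DEFAULT_SITE_SPACING) -> TemplateLibrary:
    """Default 7-class library echoing digit/letter/grid origami designs.

    The grid is a 3x4 rectangle of 12 well-separated sites (3 columns spanning
    2*spacing in x, 4 rows spanning 3*spacing in y). Digits are continuous
    chains of sites; letters are sparse, well-separated site groups.
    """
    s = spacing

    def cells(pairs):
        return np.array(pairs, float) * s

    grid = _site_grid(rows=4, cols=3, spacing=s)  # 12 sites, 2s x 3s box
    # digits: continuous strokes on a 5x7 dot matrix (col, row), one site per
    # lit cell — many sites, not well separated, like the origami digits
    digit1 = cells(
        [(2, 0), (2, 1), (2, 2), (2, 3), (2, 4), (2, 5), (2, 6), (1, 5), (1, 0), (3, 0)]
    )
    digit2 = cells(
        [(0, 5), (1, 6), (2, 6), (3, 6), (4, 5), (4, 4), (3, 3), (2, 2), (1, 1),
         (0, 0), (1, 0), (2, 0), (3, 0), (4, 0)]
    )
    digit3 = cells(
        [(1, 6), (2, 6), (3, 6), (4, 5), (4, 4), (3, 3), (2, 3), (4, 2), (4, 1),
         (3, 0), (2, 0), (1, 0)]
    )
    # letters: few well-separated site groups (~2 spacings apart)
    letter_t = cells([(-2, 4), (0, 4), (2, 4), (0, 2), (0, 0)])
    letter_o = cells([(-1.5, 3), (1.5, 3), (-1.5, 0), (1.5, 0)])
    letter_l = cells([(0, 4), (0, 2), (0, 0), (2, 0)])

    return TemplateLibrary(
        classes=[
            ("grid", grid),
            ("digit1", digit1),
            ("digit2", digit2),
            ("digit3", digit3),
            ("letterT", letter_t),
            ("letterO", letter_o),
            ("letterL", letter_l),
        ]
    )


def _rotate(points: np.ndarray, theta: float, center: np.ndarray) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return (points - center) @ rot.T + center


def sample_roi(
    layout: np.ndarray,
    params: SimulationParams,
    *,
    label: str | None = None,
    roi_extent: tuple[float, float] = DEFAULT_ROI_EXTENT,
    source_id: str | None = None,
) -> LocalizationTable:
    """Sample one ROI's localization table from a binding-site layout.

    Localizations are the union over retained sites of
    ``Normal(site, site_sigma^2 I)`` draws (count ``Poisson(locs_per_site_mean)``
    per site) plus ``Poisson(background_rate)`` uniform background draws over
    the ROI. Raises :class:`DegenerateSampleError` when the ROI ends up empty.
    """
    rng = np.random.default_rng(params.seed)
    layout = np.asarray(layout, float)
    extent = np.asarray(roi_extent, float)
    center = extent / 2.0
    sites = layout - layout.mean(axis=0) + center
    if params.rotation:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        sites = _rotate(sites, theta, center)

    keep = rng.random(len(sites)) >= params.misfold_prob
    points = []
    for site in sites[keep]:
        n = rng.poisson(params.locs_per_site_mean)
        if n:
            points.append(site + params.site_sigma * rng.standard_normal((n, 2)))
    n_bg = rng.poisson(params.background_rate)
    if n_bg:
        points.append(rng.uniform([0.0, 0.0], extent, size=(n_bg, 2)))
    if not points:
        raise DegenerateSampleError("ROI sampled zero localizations")
    xy = np.concatenate(points)
    df = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]})
    return LocalizationTable(df, gt_label=label, source_id=source_id)


def sample_dataset(
    library: TemplateLibrary,
    n_per_class: int,
    params: SimulationParams,
) -> list[LocalizationTable]:
    """Balanced dataset: exactly ``n_per_class`` ROIs of every class.

    Per-ROI seeds are spawned deterministically from ``params.seed`` so the
    whole dataset is reproducible from the single master seed.
    """
    if n_per_class < 1:
        raise PreconditionError("n_per_class must be >= 1")
    tables = []
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(len(library.classes) * n_per_class)
    idx = 0
    for name, layout in library.classes:
        for i in range(n_per_class):
            child_seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            roi_params = replace(params, seed=child_seed)
            tables.append(
                sample_roi(
                    layout,
                    roi_params,
                    label=name,
                    roi_extent=library.roi_extent,
                    source_id=f"{name}_{i:04d}",
                )
            )
    return tables


def write_dataset(
    tables: list[LocalizationTable],
    out_dir: str | Path,
    params: SimulationParams,
    dialect: str = "parquet",
) -> Path:
    """Write a dataset plus a JSON manifest listing files, labels, parameters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "parquet" if dialect == "parquet" else "csv"
    entries = []
    for table in tables:
        fname = f"{table.source_id}.{ext}"
        write_locs(table, out_dir / fname, dialect=dialect)
        entries.append({"file": fname, "gt_label": table.gt_label, "n_locs": len(table)})
    manifest = {
        "files": entries,
        "params": {
            "locs_per_site_mean": params.locs_per_site_mean,
            "site_sigma": params.site_sigma,
            "background_rate": params.background_rate,
            "misfold_prob": params.misfold_prob,
            "rotation": params.rotation,
            "seed": params.seed,
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
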
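"""Seeded generator of labeled 14-class synthetic CDDM cohorts.

No public CDDM cohort is available, so this module produces a synthetic
stand-in with the statistical structure the classifier assumes: each class
has a characteristic *spatial arrangement* of high- and low-current zones
(modelled as a sum of Gaussian blobs over the grid) and a characteristic
direction field (a constant base angle plus a linear gradient); within-class
variability is independent additive Gaussian noise on both channels.  It is
explicitly a stand-in, not a model of magnetocardiographic physics.

Class geometry.  The 14 class templates are placed in a 2-D latent space via
classical multidimensional scaling of the shortest-path distances on the
class-confusability graph (the packaged low-precision/low-sensitivity tables
plus the CAD1..CAD5 and LVH1..LVH3 severity chains).  Blob centres, base
angles and angle gradients are all affine in the latent coordinates, so
groups that the escalation rules treat as confusable really are nearby in
template space, and neighbouring severities differ by small shifts.  The
``separation`` knob in [0, 1] scales the latent coordinates: 0 collapses all
templates onto one map, 1 spreads them fully.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .core import CDDM, DEFAULT_GRID, GridConfig, wrap_angle
from .io import CohortManifest, read_manifest, write_cddm, write_manifest
from .labels import CANONICAL_ORDER, HeartStateLabel
from .rules import load_default_tables


@dataclass(frozen=True)
class Blob:
    """One Gaussian magnitude component in normalized [0,1]² coordinates."""

    center_row: float
    center_col: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.amplitude <= 0:
            raise ValueError("blob width and amplitude must be positive")


@dataclass(frozen=True)
class ClassTemplate:
    """Noise-free description of one class's magnitude and angle fields."""

    label: HeartStateLabel
    blobs: tuple[Blob, ...]
    base_angle: float
    angle_gradient: tuple[float, float]  # radians per normalized (row, col)

    def __post_init__(self) -> None:
        if not self.blobs:
            raise ValueError("template needs at least one blob")


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level settings.

    Defaults define the packaged study conditions: 40 maps per group (enough
    for one 20-per-group reference draw plus one disjoint 20-per-group
    experimental draw per cross-validation iteration), moderate within-class
    noise, and a separation that leaves the confusable class pairs genuinely
    overlapping.
    """

    templates: tuple[ClassTemplate, ...]
    magnitude_noise_sd: float = 0.05
    angle_noise_sd: float = 0.15
    per_group_count: int = 40
    seed: int = 2021
    separation: float = 0.6
    grid: GridConfig = DEFAULT_GRID

    def __post_init__(self) -> None:
        labels = [t.label for t in self.templates]
        if sorted(labels) != sorted(CANONICAL_ORDER):
            raise ValueError("config needs exactly one template per label")
        if self.magnitude_noise_sd < 0 or self.angle_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.per_group_count < 1:
            raise ValueError("per_group_count must be >= 1")
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must be in [0, 1]")

    def template_for(self, label: HeartStateLabel) -> ClassTemplate:
        for t in self.templates:
            if t.label == label:
                return t
        raise KeyError(label)


# ---------------------------------------------------------------------------
# Latent class layout
# ---------------------------------------------------------------------------

_SEVERITY_CHAINS = (
    ("CAD1", "CAD2", "CAD3", "CAD4", "CAD5"),
    ("LVH1", "LVH2", "LVH3"),
)


def _confusability_edges() -> set[frozenset[HeartStateLabel]]:
    tables = load_default_tables()
    edges: set[frozenset[HeartStateLabel]] = set()
    for table in (tables.low_precision, tables.low_sensitivity):
        for key, partners in table.items():
            for p in partners:
                edges.add(frozenset((key, p)))
    for chain in _SEVERITY_CHAINS:
        for a, b in zip(chain, chain[1:]):
            edges.add(frozenset((HeartStateLabel(a), HeartStateLabel(b))))
    return edges


def class_layout() -> dict[HeartStateLabel, tuple[float, float, float]]:
    """Deterministic 3-D latent coordinates for the 14 classes.

    Classical MDS of shortest-path distances on the confusability graph,
    centred and scaled to maximum radius 1.  Eigenvector signs are fixed so
    the layout is reproducible across runs.  Three dimensions are kept: the
    first two drive the blob positions, the third drives shape and angle
    cues, so classes a rule treats as confusable stay close in *every* cue.
    """
    n = len(CANONICAL_ORDER)
    idx = {lab: i for i, lab in enumerate(CANONICAL_ORDER)}
    adj = np.zeros((n, n))
    for edge in _confusability_edges():
        a, b = tuple(edge)
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1.0
    dist = shortest_path(adj, directed=False)
    # classical MDS (Torgerson): double-centre the squared distances
    d2 = dist**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:3]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    for col in range(coords.shape[1]):  # sign convention: largest |value| positive
        pivot = np.argmax(np.abs(coords[:, col]))
        if coords[pivot, col] < 0:
            coords[:, col] = -coords[:, col]
    coords -= coords.mean(axis=0)
    coords /= np.abs(np.linalg.norm(coords, axis=1)).max()
    return {
        lab: (float(coords[i, 0]), float(coords[i, 1]), float(coords[i, 2]))
        for lab, i in idx.items()
    }


def default_templates(separation: float = 0.6) -> tuple[ClassTemplate, ...]:
    """Build one template per class from the latent layout.

    Each class gets a primary blob at its latent position (mapped into the
    central part of the unit square), a weaker secondary blob at the mirrored
    position (two-zone structure), and an angle field whose base angle and
    gradient are affine in the latent coordinates.  The third latent
    dimension modulates blob width, secondary-blob strength and the base
    angle.
    """
    layout = class_layout()
    templates = []
    for lab in CANONICAL_ORDER:
        u, v, w = (separation * x for x in layout[lab])
        cr = 0.5 + 0.34 * u
        cc = 0.5 + 0.34 * v
        width = max(0.17 + 0.06 * w, 0.08)
        templates.append(
            ClassTemplate(
                label=lab,
                blobs=(
                    Blob(cr, cc, width, 1.0),
                    Blob(1.0 - cr, 1.0 - cc, width + 0.08, 0.45 + 0.15 * w),
                ),
                base_angle=float(np.pi * (0.9 * u + 0.5 * w)),
                angle_gradient=(2.2 * v, 2.2 * u),
            )
        )
    return tuple(templates)


def default_config(
    separation: float = 0.6,
    magnitude_noise_sd: float = 0.05,
    angle_noise_sd: float = 0.15,
    per_group_count: int = 40,
    seed: int = 2021,
    grid: GridConfig = DEFAULT_GRID,
) -> GeneratorConfig:
    """The packaged default cohort conditions."""
    return GeneratorConfig(
        templates=default_templates(separation),
        magnitude_noise_sd=magnitude_noise_sd,
        angle_noise_sd=angle_noise_sd,
        per_group_count=per_group_count,
        seed=seed,
        separation=separation,
        grid=grid,
    )


def templates_from_file(path: str | Path) -> tuple[ClassTemplate, ...]:
    """Load class templates from a YAML file.

    Expected structure: a top-level ``templates`` list (or bare list), one
    entry per class::

        templates:
          - label: NORM1
            blobs:
              - {center_row: 0.4, center_col: 0.6, width: 0.2, amplitude: 1.0}
            base_angle: 0.3
            angle_gradient: [0.5, -0.2]
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    items = raw.get("templates", raw) if isinstance(raw, dict) else raw
    if not isinstance(items, list):
        raise ValueError(f"{path}: expected a list of templates")
    from .labels import parse_label

    templates = []
    for item in items:
        blobs = tuple(
            Blob(
                center_row=float(b["center_row"]),
                center_col=float(b["center_col"]),
                width=float(b["width"]),
                amplitude=float(b.get("amplitude", 1.0)),
            )
            for b in item["blobs"]
        )
        d_row, d_col = item.get("angle_gradient", (0.0, 0.0))
        templates.append(
            ClassTemplate(
                label=parse_label(str(item["label"])),
                blobs=blobs,
                base_angle=float(item.get("base_angle", 0.0)),
                angle_gradient=(float(d_row), float(d_col)),
            )
        )
    return tuple(templates)


# ---------------------------------------------------------------------------
# Rendering and sampling
# ---------------------------------------------------------------------------


def render_template(template: ClassTemplate, grid: GridConfig = DEFAULT_GRID) -> CDDM:
    """Noise-free map of a template on the given grid (deterministic)."""
    h, w = grid.height, grid.width
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    r = rows / (h - 1)
    c = cols / (w - 1)
    mag = np.zeros((h, w))
    for blob in template.blobs:
        d2 = (r - blob.center_row) ** 2 + (c - blob.center_col) ** 2
        mag = mag + blob.amplitude * np.exp(-d2 / (2.0 * blob.width**2))
    d_row, d_col = template.angle_gradient
    ang = wrap_angle(template.base_angle + d_row * rows / h + d_col * cols / w)
    return CDDM(
        magnitude=mag,
        angle=np.broadcast_to(ang, (h, w)).copy(),
        label=template.label,
        map_id=f"{template.label.value}_template",
    )


def sample_map(
    template: ClassTemplate,
    config: GeneratorConfig,
    rng: np.random.Generator,
    map_id: str = "",
) -> CDDM:
    """One noisy draw from a template.

    Gaussian noise is added independently per node to the magnitudes
    (clipped at 0, then re-normalized) and to the angles (re-wrapped).
    """
    clean = render_template(template, config.grid)
    mag = clean.magnitude
    ang = clean.angle
    if config.magnitude_noise_sd > 0:
        mag = np.clip(mag + rng.normal(0.0, config.magnitude_noise_sd, mag.shape), 0.0, None)
    if config.angle_noise_sd > 0:
        ang = wrap_angle(ang + rng.normal(0.0, config.angle_noise_sd, ang.shape))
    return CDDM(magnitude=mag, angle=ang, label=template.label, map_id=map_id)


def _draw_rng(seed: int, label_index: int, draw_index: int) -> np.random.Generator:
    # independent stream per (seed, class, draw): reproducible regardless of
    # generation order
    return np.random.default_rng(np.random.SeedSequence([seed, label_index, draw_index]))


def generate_maps(config: GeneratorConfig) -> list[CDDM]:
    """Generate the full cohort in memory: per_group_count maps per class."""
    maps: list[CDDM] = []
    for li, lab in enumerate(CANONICAL_ORDER):
        template = config.template_for(lab)
        for d in range(config.per_group_count):
            rng = _draw_rng(config.seed, li, d)
            maps.append(sample_map(template, config, rng, map_id=f"{lab.value}_{d:03d}"))
    return maps


def generate_cohort(config: GeneratorConfig, out_dir: str | Path) -> CohortManifest:
    """Write the cohort (map files + ``manifest.tsv``) and load it back."""
    out_dir = Path(out_dir)
    maps_dir = out_dir / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    from .io import ManifestEntry  # local import to avoid cycle at module load

    entries = []
    for cddm in generate_maps(config):
        mag_path, ang_path = write_cddm(cddm, maps_dir)
        entries.append(
            ManifestEntry(
                map_id=cddm.map_id,
                magnitude_path=mag_path,
                angle_path=ang_path,
                label=cddm.label,
            )
        )
    manifest_path = out_dir / "manifest.tsv"
    write_manifest(CohortManifest(entries=entries), manifest_path)
    return read_manifest(manifest_path)
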
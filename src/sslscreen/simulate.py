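"""Synthetic two-arm siRNA screens with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
207-gene library with three siRNAs per gene arrayed in 384-well plates
alongside mock, non-targeting, and cytotoxic (KIF11-like) control wells;
two arms (query-depleted vs. query-proficient); three biological x two
technical replicates; and per-well nucleus counts built as

    expected = baseline * plate_factor * edge(col) * well_noise
               * V_a(siRNA) * [depleted arm: V_b * (1 - delta if planted)]
    count    ~ Poisson(expected)

Per-siRNA single-knockdown viability is V_a = 1 - efficacy * (1 - g) where
g is the target gene's knockout viability and efficacy ~ Beta(alpha, beta)
models incomplete knockdown. Most genes are near-neutral; a configurable
fraction is mildly growth-impairing, as expected of a DNA-damage-response
library. A subset of genes is planted as synthetic sick/lethal
interactors: in the depleted arm only, their wells' expectation is
multiplied by (1 - delta).

With ``noise_free=True`` all stochastic factors are fixed at 1 and the
Poisson draw is replaced by its mean, so every count equals its closed-form
expectation exactly (counts are then floats) and downstream epsilon scores
can be checked against the analytic values in the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError
from .model import (
    ARMS,
    PLATE_COLS,
    PLATE_ROWS,
    MEASUREMENT_COLUMNS,
    SiRNALibrary,
    ScreenDesign,
    validate_measurements,
    well_label,
)

#: per plate: 8 mock + 8 non-targeting + 8 cytotoxic-positive control wells
CONTROLS_PER_PLATE = {"mock": 8, "nontargeting": 8, "cytotoxic_positive": 8}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic screen.

    Defaults mirror the screen design being emulated: 207 genes x 3
    siRNAs, 384-well plates, 9 imaging fields per well, 3 biological x 2
    technical replicates, a query knockdown that leaves 60% of cells
    (``query_effect``), and 10 planted synthetic sick/lethal genes whose
    combined-arm viability is halved (``interaction_strength`` = 0.5).
    """

    n_genes: int = 207
    sirnas_per_gene: int = 3
    plate_format: int = 384
    n_fields_per_well: int = 9
    n_bio_reps: int = 3
    n_tech_reps: int = 2
    baseline_count: float = 1500.0
    query_effect: float = 0.6
    n_interactors: int = 10
    interaction_strength: float = 0.5
    efficacy_alpha: float = 8.0
    efficacy_beta: float = 2.0
    fraction_deleterious: float = 0.35
    deleterious_viability: tuple[float, float] = (0.3, 0.9)
    neutral_sigma: float = 0.02
    well_sigma: float = 0.1
    plate_sigma: float = 0.05
    edge_gradient: float = 0.0
    cytotoxic_control_viability: float = 0.05
    gene_viability_overrides: dict[str, float] = field(default_factory=dict)
    noise_free: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.sirnas_per_gene < 1:
            raise ConfigurationError("library dimensions must be >= 1")
        if self.plate_format != 384:
            raise ConfigurationError("only 384-well plates are supported")
        if self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ConfigurationError("replicate counts must be >= 1")
        if not 0 < self.query_effect <= 1:
            raise ConfigurationError("query_effect must be in (0, 1]")
        if not 0 <= self.interaction_strength <= 1:
            raise ConfigurationError("interaction_strength must be in [0, 1]")
        if self.n_interactors > self.n_genes:
            raise ConfigurationError("more planted interactors than genes")
        if self.baseline_count <= 0:
            raise ConfigurationError("baseline_count must be positive")
        for name in ("well_sigma", "plate_sigma"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.fraction_deleterious <= 1:
            raise ConfigurationError("fraction_deleterious must be in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["deleterious_viability"] = list(self.deleterious_viability)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "deleterious_viability" in d:
            d["deleterious_viability"] = tuple(d["deleterious_viability"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc


@dataclass
class GroundTruth:
    """Everything needed to check the analysis against the generator.

    ``sirna_table.expected_epsilon`` is the closed-form aggregate epsilon
    on the analysis scale (sqrt-transformed, percent-of-control): because
    the square root distributes over products, a count-scale multiplier
    (1 - delta) on V_ab appears as sqrt(1 - delta) after normalization, so

        expected_epsilon = sqrt(V_a * V_b) * (sqrt(1 - delta_s) - 1)

    with delta_s = delta for planted genes' siRNAs and 0 otherwise.
    """

    gene_table: pd.DataFrame   # gene, viability, deleterious, planted
    sirna_table: pd.DataFrame  # sirna_id, gene, efficacy, v_a, planted, expected_epsilon
    true_v_b: float
    delta: float
    plate_factors: pd.DataFrame  # plate_id, arm, bio_rep, tech_rep, factor
    config: SimulationConfig

    @property
    def planted_genes(self) -> set[str]:
        return set(self.gene_table.loc[self.gene_table["planted"], "gene"])


def default_library(
    n_genes: int = 207, sirnas_per_gene: int = 3
) -> SiRNALibrary:
    """A synthetic library: genes G001..G207, siRNAs G001_s1..G001_s3 etc."""
    width = max(3, len(str(n_genes)))
    rows = [
        {"sirna_id": f"G{g:0{width}d}_s{s}", "gene": f"G{g:0{width}d}"}
        for g in range(1, n_genes + 1)
        for s in range(1, sirnas_per_gene + 1)
    ]
    return SiRNALibrary(pd.DataFrame(rows))


def build_plate_layouts(library: SiRNALibrary) -> pd.DataFrame:
    """Array the library across as many 384-well plates as needed.

    Control wells sit at every 16th row-major position (24 slots per
    plate), cycling mock / non-targeting / cytotoxic so each role gets 8
    spatially spread wells; the remaining 360 positions take siRNAs in
    library order. Returns columns plate_id, well, row, col, content.
    Unused trailing positions on the last plate are left out.
    """
    n_wells = len(PLATE_ROWS) * PLATE_COLS
    control_slots = {i * 16 for i in range(24)}
    roles = ("mock", "nontargeting", "cytotoxic_positive")
    sample_capacity = n_wells - len(control_slots)
    sirnas = library.sirna_ids
    n_plates = math.ceil(len(sirnas) / sample_capacity)
    rows = []
    cursor = 0
    for p in range(1, n_plates + 1):
        plate_id = f"P{p:02d}"
        ctrl_i = 0
        for idx in range(n_wells):
            r, c = PLATE_ROWS[idx // PLATE_COLS], idx % PLATE_COLS + 1
            if idx in control_slots:
                content = roles[ctrl_i % 3]
                ctrl_i += 1
            elif cursor < len(sirnas):
                content = sirnas[cursor]
                cursor += 1
            else:
                continue  # unused position, not plated
            rows.append({
                "plate_id": plate_id, "well": well_label(r, c),
                "row": r, "col": c, "content": content,
            })
    return pd.DataFrame(rows)


def simulate_screen(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one full synthetic screen and its ground truth.

    Returns a validated long-format measurement table (one row per well
    per arm per replicate) and the :class:`GroundTruth`. Identical
    configurations (including seed) give identical tables.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    truth_ss, plates_ss = root.spawn(2)
    rng = np.random.default_rng(truth_ss)

    library = default_library(cfg.n_genes, cfg.sirnas_per_gene)
    genes = library.genes

    # --- gene knockout viabilities: mostly near-neutral, some deleterious
    deleterious = rng.random(cfg.n_genes) < cfg.fraction_deleterious
    lo, hi = cfg.deleterious_viability
    g_viab = np.where(
        deleterious,
        rng.uniform(lo, hi, cfg.n_genes),
        np.clip(1.0 - np.abs(rng.normal(0.0, cfg.neutral_sigma, cfg.n_genes)), 0, 1),
    )
    # overrides plant a gene's knockdown effect exactly: its siRNAs get
    # efficacy 1, so each well's V_a equals the stated viability
    for gene, v in cfg.gene_viability_overrides.items():
        if gene not in genes:
            raise ConfigurationError(f"override for unknown gene {gene!r}")
        g_viab[genes.index(gene)] = float(v)

    # --- planted synthetic sick/lethal interactors
    planted_idx = rng.choice(cfg.n_genes, size=cfg.n_interactors, replace=False)
    planted = np.zeros(cfg.n_genes, dtype=bool)
    planted[planted_idx] = True

    gene_table = pd.DataFrame({
        "gene": genes,
        "viability": g_viab,
        "deleterious": deleterious,
        "planted": planted,
    })

    # --- per-siRNA efficacy and single-knockdown viability
    efficacy = rng.beta(
        cfg.efficacy_alpha, cfg.efficacy_beta, len(library.sirna_ids)
    )
    if cfg.gene_viability_overrides:
        overridden = library.entries["gene"].isin(
            cfg.gene_viability_overrides
        ).to_numpy()
        efficacy = np.where(overridden, 1.0, efficacy)
    sirna_table = library.entries.copy()
    sirna_table["efficacy"] = efficacy
    gmap = gene_table.set_index("gene")
    sirna_table["v_a"] = 1.0 - efficacy * (
        1.0 - gmap.loc[sirna_table["gene"], "viability"].to_numpy()
    )
    sirna_table["planted"] = gmap.loc[
        sirna_table["gene"], "planted"
    ].to_numpy()
    delta_s = np.where(sirna_table["planted"], cfg.interaction_strength, 0.0)
    sirna_table["expected_epsilon"] = np.sqrt(
        sirna_table["v_a"] * cfg.query_effect
    ) * (np.sqrt(1.0 - delta_s) - 1.0)

    # --- realize counts plate by plate
    layout = build_plate_layouts(library)
    v_a_map = dict(zip(sirna_table["sirna_id"], sirna_table["v_a"]))
    v_a_map["mock"] = 1.0
    v_a_map["nontargeting"] = 1.0
    v_a_map["cytotoxic_positive"] = cfg.cytotoxic_control_viability
    planted_sirnas = set(sirna_table.loc[sirna_table["planted"], "sirna_id"])

    base_v = layout["content"].map(v_a_map).to_numpy()
    interacting = layout["content"].isin(planted_sirnas).to_numpy()
    edge = 1.0 + cfg.edge_gradient * (
        (layout["col"].to_numpy() - (PLATE_COLS + 1) / 2) / ((PLATE_COLS - 1) / 2)
    )

    plate_ids = list(dict.fromkeys(layout["plate_id"]))
    n_physical = cfg.n_bio_reps * cfg.n_tech_reps * len(ARMS) * len(plate_ids)
    streams = plates_ss.spawn(n_physical)

    chunks = []
    factor_rows = []
    k = 0
    for bio in range(1, cfg.n_bio_reps + 1):
        for tech in range(1, cfg.n_tech_reps + 1):
            for arm in ARMS:
                for plate_id in plate_ids:
                    prng = np.random.default_rng(streams[k])
                    k += 1
                    sel = layout["plate_id"] == plate_id
                    v = base_v[sel.to_numpy()]
                    inter = interacting[sel.to_numpy()]
                    e = edge[sel.to_numpy()]
                    if arm == "query_depleted":
                        v = v * cfg.query_effect
                        v = np.where(inter, v * (1.0 - cfg.interaction_strength), v)
                    if cfg.noise_free:
                        pf = 1.0
                        expected = cfg.baseline_count * pf * e * v
                        counts = expected
                    else:
                        pf = float(np.exp(prng.normal(0.0, cfg.plate_sigma)))
                        wn = np.exp(prng.normal(0.0, cfg.well_sigma, v.shape))
                        expected = cfg.baseline_count * pf * e * wn * v
                        counts = prng.poisson(expected).astype(float)
                    chunk = layout[sel].copy()
                    chunk["arm"] = arm
                    chunk["bio_rep"] = bio
                    chunk["tech_rep"] = tech
                    chunk["nuclei_count"] = counts
                    chunks.append(chunk)
                    factor_rows.append({
                        "plate_id": plate_id, "arm": arm,
                        "bio_rep": bio, "tech_rep": tech, "factor": pf,
                    })

    measurements = pd.concat(chunks, ignore_index=True)[MEASUREMENT_COLUMNS]
    design = ScreenDesign(library, cfg.n_bio_reps, cfg.n_tech_reps)
    measurements = validate_measurements(measurements, design)

    truth = GroundTruth(
        gene_table=gene_table,
        sirna_table=sirna_table,
        true_v_b=cfg.query_effect,
        delta=cfg.interaction_strength,
        plate_factors=pd.DataFrame(factor_rows),
        config=cfg,
    )
    return measurements, truth


def write_truth(truth: GroundTruth, outdir: str | Path) -> None:
    """Write ground-truth tables (and config) next to a simulated screen."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.gene_table.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    truth.sirna_table.to_csv(outdir / "truth_sirnas.tsv", sep="\t", index=False)
    truth.plate_factors.to_csv(outdir / "truth_plates.tsv", sep="\t", index=False)
    truth.config.to_yaml(outdir / "config.yaml")


# ---------------------------------------------------------------------------
# synthetic well images for the nuclei-counting front end

def render_well_images(
    n_nuclei: int,
    image_size: tuple[int, int] = (128, 128),
    n_fields: int = 9,
    seed: int = 0,
    radius: float = 4.0,
    peak: int = 30000,
    background: int = 800,
) -> tuple[list[np.ndarray], list[int]]:
    """Render a well's fields as 16-bit images of non-overlapping nuclei.

    ``n_nuclei`` are split across fields multinomially; each nucleus is a
    bright disc with Gaussian falloff at a rejection-sampled position kept
    at least 3 radii from its neighbours (no overlaps, so a simple counter
    can recover the truth exactly). Returns (images, per-field counts);
    the counts sum to ``n_nuclei``. Raises if the requested density
    exceeds the non-overlap capacity of a field.
    """
    if n_nuclei < 0:
        raise ValidationError("n_nuclei must be >= 0")
    if n_fields < 1:
        raise ValidationError("n_fields must be >= 1")
    h, w = image_size
    if h < 64 or w < 64:
        raise ValidationError("fields must be at least 64x64 pixels")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    field_counts = rng.multinomial(n_nuclei, [1.0 / n_fields] * n_fields)

    min_sep = 3.0 * radius
    margin = 2.0 * radius
    cap = math.floor((h - 2 * margin) / min_sep + 1) * math.floor(
        (w - 2 * margin) / min_sep + 1
    )
    if field_counts.max() > cap:
        raise ValidationError(
            f"field of {field_counts.max()} nuclei exceeds non-overlap "
            f"capacity {cap} for {h}x{w} at radius {radius}"
        )

    sigma = radius / 1.5
    extent = int(math.ceil(2.5 * sigma))
    yy, xx = np.mgrid[-extent:extent + 1, -extent:extent + 1]
    kernel = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))

    images = []
    for count in field_counts:
        img = np.full((h, w), float(background))
        centers: list[tuple[float, float]] = []
        for _ in range(int(count)):
            for _attempt in range(10000):
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
                if all(
                    (cy - oy) ** 2 + (cx - ox) ** 2 >= min_sep**2
                    for oy, ox in centers
                ):
                    centers.append((cy, cx))
                    break
            else:  # pragma: no cover - capacity check makes this unreachable
                raise ValidationError("could not place nucleus without overlap")
            iy, ix = int(round(cy)), int(round(cx))
            y0, y1 = iy - extent, iy + extent + 1
            x0, x1 = ix - extent, ix + extent + 1
            img[max(y0, 0):y1, max(x0, 0):x1] += (
                peak * kernel[max(y0, 0) - y0:(2 * extent + 1) - max(y1 - h, 0),
                              max(x0, 0) - x0:(2 * extent + 1) - max(x1 - w, 0)]
            )
        images.append(np.clip(img, 0, 65535).astype(np.uint16))
    return images, [int(c) for c in field_counts]


def write_well_images(
    images: list[np.ndarray], plate_id: str, well: str, outdir: str | Path
) -> list[Path]:
    """Write field images as ``<plate>_<well>_f<index>.tif`` files."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images, start=1):
        path = outdir / f"{plate_id}_{well}_f{i}.tif"
        tifffile.imwrite(path, img)
        paths.append(path)
    return paths
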
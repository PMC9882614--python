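"""Synthetic tissue, cohort and survival generators with planted ground truth.

The tissue generator emulates multiplexed-imaging tissue-microarray cores:
each region holds one or more tumor nests, macrophage subtypes placed at
controlled mean distances from the nearest tumor cell, and stromal cells
scattered uniformly. Nuclei are hard discs rendered into a label mask; a
marker intensity stack is the sum of per-pixel Gaussian background and a
type-dependent log-normal signal painted over each nucleus.

Cohort generators emulate the tabular side of the analysis: per-sample
cell-cluster count tables with planted between-group frequency ratios, and
multi-dataset expression/overall-survival cohorts where a gene-signature
score carries a planted log hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.draw import disk

__all__ = [
    "CellTypeSpec",
    "SimTissueConfig",
    "SimCohortConfig",
    "GroundTruth",
    "SurvivalCohort",
    "simulate_tissue",
    "simulate_frequency_cohort",
    "simulate_survival_cohorts",
    "simulate_grouped_measurements",
    "make_marker_model",
    "default_tissue_config",
    "typing_tissue_config",
]


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellTypeSpec:
    """One simulated cell population within each region.

    placement:
        ``("in_nest",)`` — uniform inside a randomly chosen tumor nest;
        ``("ring", d_mean_um, d_sd_um)`` — outside the nests at a Gaussian
        distance (in microns) from the closest tumor cell;
        ``("uniform",)`` — uniform over the whole region.
    """

    name: str
    count_per_region: int
    placement: tuple


@dataclass(frozen=True)
class SimTissueConfig:
    image_shape: tuple = (600, 600)
    n_regions: int = 3
    microns_per_pixel: float = 0.5
    tumor_nests: tuple = (((170.0, 170.0), 95.0), ((430.0, 410.0), 110.0))
    cell_types: tuple = ()
    nucleus_radius: int = 4
    marker_model: Mapping[str, Mapping[str, tuple]] = field(default_factory=dict)
    markers: tuple = ()
    background_mean: float = 5.0
    background_sd: float = 2.0
    tumor_type: str = "Tumor"
    niche_band_um: float = 60.0
    max_retries: int = 1000
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0 or self.n_regions <= 0:
            raise ValueError("image shape and n_regions must be positive")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be positive")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        for (cy, cx), r in self.tumor_nests:
            if r <= 0:
                raise ValueError("tumor nest radii must be positive")
        names = [t.name for t in self.cell_types]
        if len(set(names)) != len(names):
            raise ValueError("cell type names must be unique")
        for t in self.cell_types:
            if t.count_per_region < 0:
                raise ValueError(f"negative count for type {t.name!r}")
            kind = t.placement[0]
            if kind == "ring":
                _, d_mean, d_sd = t.placement
                if d_mean <= 0 or d_sd < 0:
                    raise ValueError(f"invalid ring placement for {t.name!r}")
                # feasibility: some arc of the planted ring must lie inside
                # the image around at least one nest
                d_px = d_mean / self.microns_per_pixel
                fits = False
                for (cy, cx), r in self.tumor_nests:
                    corner = max(
                        np.hypot(cy - yy, cx - xx)
                        for yy in (0.0, float(h)) for xx in (0.0, float(w))
                    )
                    if r + d_px < corner:
                        fits = True
                if not fits:
                    raise ValueError(
                        f"ring placement for {t.name!r} does not fit inside the image"
                    )
            elif kind not in ("in_nest", "uniform"):
                raise ValueError(f"unknown placement {kind!r} for {t.name!r}")


@dataclass(frozen=True)
class SimCohortConfig:
    n_samples_per_group: int = 50
    clusters: tuple = ("NLRP3 TAM", "SPP1 TAM", "IL4I1 TAM", "FOLR2 TRM", "Monocyte")
    dirichlet_base: tuple = (0.02, 0.18, 0.25, 0.25, 0.30)
    planted_log2_ratio: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    concentration: float = 80.0
    cells_per_sample: tuple = (60, 400)
    n_datasets: int = 4
    samples_per_dataset: int = 100
    signature_genes: tuple = tuple(f"SIG{i}" for i in range(10))
    noise_genes: tuple = tuple(f"NOISE{i}" for i in range(40))
    planted_log_hazard: float = 0.0
    censoring_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_group < 2 or self.samples_per_dataset < 2:
            raise ValueError("sample counts must be >= 2")
        if len(self.dirichlet_base) != len(self.clusters):
            raise ValueError("dirichlet_base must match clusters")
        if len(self.planted_log2_ratio) != len(self.clusters):
            raise ValueError("planted_log2_ratio must match clusters")
        if any(a <= 0 for a in self.dirichlet_base):
            raise ValueError("Dirichlet concentrations must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        lo, hi = self.cells_per_sample
        if lo <= 0 or hi < lo:
            raise ValueError("cells_per_sample must be a positive (lo, hi) range")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated object."""

    cell_type: pd.Series | None = None
    niche_id: pd.Series | None = None
    planted_distance_um: dict = field(default_factory=dict)
    group_log2_ratio: dict = field(default_factory=dict)
    log_hazard: float | None = None

    def to_json_dict(self) -> dict:
        out: dict = {
            "planted_distance_um": self.planted_distance_um,
            "group_log2_ratio": self.group_log2_ratio,
            "log_hazard": self.log_hazard,
        }
        if self.cell_type is not None:
            out["cell_type"] = self.cell_type.tolist()
        if self.niche_id is not None:
            out["niche_id"] = self.niche_id.tolist()
        return out


@dataclass
class SurvivalCohort:
    """One dataset: normalized expression plus overall survival."""

    dataset_id: str
    expression: pd.DataFrame  # genes x samples
    survival: pd.DataFrame    # columns: sample_id, time, event

    @property
    def n(self) -> int:
        return self.survival.shape[0]


# --------------------------------------------------------------------------
# marker model helpers
# --------------------------------------------------------------------------

def make_marker_model(
    positive_markers: Mapping[str, Sequence[str]],
    markers: Sequence[str],
    separation: float = 2.0,
    base_log: float = 3.9,
    sigma_log: float = 0.25,
) -> dict:
    """Build a per-(type, marker) log-intensity model from a marker table.

    Positive markers of a type sit at ``base_log + separation * sigma_log``
    and all others at ``base_log - separation * sigma_log``, so
    ``separation`` is the half-gap between the positive and negative
    populations in units of the within-population log-sd.
    """
    model = {}
    for ctype, pos in positive_markers.items():
        model[ctype] = {
            m: (
                base_log + (separation if m in pos else -separation) * sigma_log,
                sigma_log,
            )
            for m in markers
        }
    return model


_DEFAULT_MARKERS = ("PanCK", "FOLR2", "IL4I1", "SPP1")
_DEFAULT_POSITIVE = {
    "Tumor": ("PanCK",),
    "IL4I1 TAM": ("IL4I1",),
    "SPP1 TAM": ("SPP1",),
    "FOLR2 TRM": ("FOLR2",),
}


def default_tissue_config(seed: int = 0, separation: float = 2.0) -> SimTissueConfig:
    """Study-condition default: 3 regions of ~1,000 cells each.

    Two tumor nests per region; SPP1 and IL4I1 macrophages planted near the
    tumor boundary, FOLR2 resident macrophages planted distal, stroma uniform.
    """
    cell_types = (
        CellTypeSpec("Tumor", 420, ("in_nest",)),
        CellTypeSpec("IL4I1 TAM", 130, ("ring", 38.0, 10.0)),
        CellTypeSpec("SPP1 TAM", 130, ("ring", 36.0, 10.0)),
        CellTypeSpec("FOLR2 TRM", 130, ("ring", 100.0, 15.0)),
        CellTypeSpec("Stroma", 190, ("uniform",)),
    )
    markers = _DEFAULT_MARKERS
    positive = dict(_DEFAULT_POSITIVE)
    positive["Stroma"] = ()
    return SimTissueConfig(
        cell_types=cell_types,
        markers=markers,
        marker_model=make_marker_model(positive, markers, separation=separation),
        seed=seed,
    )


def typing_tissue_config(seed: int = 0, separation: float = 2.0,
                         count_per_type: int = 250) -> SimTissueConfig:
    """Balanced four-type tissue used to benchmark the typing pipeline.

    Equal counts of tumor cells and the three macrophage populations, each
    with one dedicated marker; ``separation`` is the half-gap between the
    positive and negative log-intensity means in units of the log-sd.
    """
    cell_types = (
        CellTypeSpec("Tumor", count_per_type, ("in_nest",)),
        CellTypeSpec("IL4I1 TAM", count_per_type, ("ring", 38.0, 10.0)),
        CellTypeSpec("SPP1 TAM", count_per_type, ("ring", 36.0, 10.0)),
        CellTypeSpec("FOLR2 TRM", count_per_type, ("ring", 100.0, 15.0)),
    )
    return SimTissueConfig(
        cell_types=cell_types,
        markers=_DEFAULT_MARKERS,
        marker_model=make_marker_model(
            _DEFAULT_POSITIVE, _DEFAULT_MARKERS, separation=separation
        ),
        seed=seed,
    )


# --------------------------------------------------------------------------
# tissue simulation
# --------------------------------------------------------------------------

def _place_disc(rng, proposal, placed, min_dist2, max_retries, bounds, type_name):
    """Rejection-sample one non-overlapping nucleus centre."""
    h, w, margin = bounds
    for _ in range(max_retries):
        cy, cx = proposal(rng)
        if not (margin <= cy < h - margin and margin <= cx < w - margin):
            continue
        if placed:
            arr = np.asarray(placed)
            d2 = (arr[:, 0] - cy) ** 2 + (arr[:, 1] - cx) ** 2
            if (d2 < min_dist2).any():
                continue
        return cy, cx
    raise RuntimeError(
        f"could not place a nucleus of type {type_name!r} after {max_retries} retries; "
        "the region is too crowded"
    )


def _ring_proposal(rng, nests, tumor_tree, d_px):
    """Position at planted distance d_px from the closest tumor cell.

    A point is proposed on a nest boundary offset radially by d_px, then
    corrected toward/away from its actual nearest tumor cell so the planted
    distance is realised against the cells, not the nominal boundary.
    """
    perims = np.array([r for _, r in nests], dtype=float)
    i = rng.choice(len(nests), p=perims / perims.sum())
    (cy, cx), r = nests[i]
    theta = rng.uniform(0, 2 * np.pi)
    u = np.array([np.sin(theta), np.cos(theta)])
    pos = np.array([cy, cx]) + (r + d_px) * u
    for _ in range(3):
        dist, j = tumor_tree.query(pos)
        anchor = tumor_tree.data[j]
        v = pos - anchor
        norm = np.hypot(*v)
        if norm < 1e-9:
            break
        pos = anchor + v / norm * d_px
    return pos[0], pos[1]


def simulate_tissue(config: SimTissueConfig):
    """Render synthetic tissue regions.

    Returns
    -------
    mask:
        uint16 array ``(n_regions, H, W)`` of nucleus labels, globally unique.
    stack:
        float32 array ``(n_regions, n_channels, H, W)`` of marker intensities.
    cells:
        CellTable DataFrame: cell_id, region_id, x/y in px and um, true
        ``cell_type`` and per-marker signal intensity of each cell.
    truth:
        GroundTruth with per-cell type, geometric niche id (0 = inside a
        nest, 1 = within ``niche_band_um`` of a nest boundary, 2 = distal)
        and the planted mean distances of ring-placed types.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    mpp = config.microns_per_pixel
    r_nuc = config.nucleus_radius
    min_dist2 = float((2 * r_nuc + 1) ** 2)
    bounds = (h, w, r_nuc + 1)
    nests = [((float(cy), float(cx)), float(r)) for (cy, cx), r in config.tumor_nests]
    areas = np.array([r * r for _, r in nests])

    n_channels = len(config.markers)
    mask = np.zeros((config.n_regions, h, w), dtype=np.uint16)
    stack = np.zeros((config.n_regions, n_channels, h, w), dtype=np.float32)

    rows = []
    label = 0
    # ring types need tumor cells in place first
    first_pass = [t for t in config.cell_types if t.placement[0] != "ring"]
    second_pass = [t for t in config.cell_types if t.placement[0] == "ring"]

    for region in range(config.n_regions):
        placed: list[tuple[float, float]] = []
        region_rows = []

        def in_nest_proposal(rng):
            i = rng.choice(len(nests), p=areas / areas.sum())
            (cy, cx), r = nests[i]
            rad = (r - r_nuc - 1) * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            return cy + rad * np.sin(th), cx + rad * np.cos(th)

        def uniform_proposal(rng):
            return rng.uniform(0, h), rng.uniform(0, w)

        for spec in first_pass:
            prop = in_nest_proposal if spec.placement[0] == "in_nest" else uniform_proposal
            for _ in range(spec.count_per_region):
                cy, cx = _place_disc(
                    rng, prop, placed, min_dist2, config.max_retries, bounds, spec.name
                )
                placed.append((cy, cx))
                region_rows.append((spec.name, cy, cx))

        tumor_pts = np.array(
            [(cy, cx) for (name, cy, cx) in region_rows if name == config.tumor_type]
        )
        if second_pass and len(tumor_pts) == 0:
            raise ValueError(
                f"ring placement requires cells of tumor_type {config.tumor_type!r}"
            )
        tumor_tree = cKDTree(tumor_pts) if len(tumor_pts) else None

        for spec in second_pass:
            _, d_mean, d_sd = spec.placement
            for _ in range(spec.count_per_region):
                def prop(rng):
                    d_um = max(rng.normal(d_mean, d_sd), 2.0)
                    return _ring_proposal(rng, nests, tumor_tree, d_um / mpp)
                cy, cx = _place_disc(
                    rng, prop, placed, min_dist2, config.max_retries, bounds, spec.name
                )
                placed.append((cy, cx))
                region_rows.append((spec.name, cy, cx))

        # rasterize in placement order so labels are deterministic
        background = rng.normal(
            config.background_mean, config.background_sd, size=(n_channels, h, w)
        )
        for name, cy, cx in region_rows:
            label += 1
            rr, cc = disk((cy, cx), r_nuc + 0.5, shape=(h, w))
            mask[region, rr, cc] = label
            signals = []
            for ci, m in enumerate(config.markers):
                mu, sigma = config.marker_model[name][m]
                v = float(np.exp(rng.normal(mu, sigma)))
                background[ci, rr, cc] += v
                signals.append(v)
            rows.append((label, region, cx, cy, name, *signals))
        stack[region] = np.clip(background, 0.0, None)

    cells = pd.DataFrame(
        rows,
        columns=["cell_id", "region_id", "x_px", "y_px", "cell_type", *config.markers],
    )
    cells.insert(4, "x_um", cells["x_px"] * mpp)
    cells.insert(5, "y_um", cells["y_px"] * mpp)

    # geometric niche truth: nest interior / peri-nest band / distal
    niche = np.full(len(cells), 2, dtype=int)
    yx = cells[["y_px", "x_px"]].to_numpy()
    boundary = np.full(len(cells), np.inf)
    for (cy, cx), r in nests:
        d_center = np.hypot(yx[:, 0] - cy, yx[:, 1] - cx)
        boundary = np.minimum(boundary, d_center - r)
    band_px = config.niche_band_um / mpp
    niche[boundary <= band_px] = 1
    niche[boundary <= 0] = 0
    cells["true_niche"] = niche

    truth = GroundTruth(
        cell_type=cells["cell_type"].copy(),
        niche_id=pd.Series(niche),
        planted_distance_um={
            t.name: t.placement[1] for t in second_pass
        },
    )
    return mask, stack, cells, truth


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

def _group_mean_freqs(config: SimCohortConfig):
    """Expected cluster frequencies per group realizing the planted ratios.

    Group B keeps the base frequencies. In group A each cluster with a
    nonzero planted log2 ratio is scaled exactly by 2**ratio; the remaining
    probability mass is shared among the unshifted clusters proportionally,
    so planted ratios are exact in expectation and unshifted clusters absorb
    a common (small) renormalization.
    """
    base = np.asarray(config.dirichlet_base, dtype=float)
    p_b = base / base.sum()
    ratios = np.asarray(config.planted_log2_ratio, dtype=float)
    shifted = ratios != 0
    q = p_b.copy()
    q[shifted] = p_b[shifted] * 2.0 ** ratios[shifted]
    mass = q[shifted].sum()
    if mass >= 1.0:
        raise ValueError("planted ratios push shifted clusters past total frequency 1")
    q[~shifted] = p_b[~shifted] * (1.0 - mass) / p_b[~shifted].sum()
    return q, p_b


def simulate_frequency_cohort(config: SimCohortConfig):
    """Per-sample cluster count tables for two groups, Dirichlet-multinomial.

    Returns a tidy counts DataFrame (sample_id, group, one column per
    cluster) and the GroundTruth holding the planted per-cluster log2
    mean-frequency ratios (group A over group B).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    q_a, p_b = _group_mean_freqs(config)
    lo, hi = config.cells_per_sample
    rows = []
    for group, probs in (("A", q_a), ("B", p_b)):
        alpha = probs * config.concentration
        for i in range(config.n_samples_per_group):
            p = rng.dirichlet(alpha)
            total = int(rng.integers(lo, hi + 1))
            counts = rng.multinomial(total, p)
            rows.append((f"{group}{i:03d}", group, *counts))
    table = pd.DataFrame(rows, columns=["sample_id", "group", *config.clusters])
    truth = GroundTruth(
        group_log2_ratio={
            c: float(np.log2(q_a[j] / p_b[j])) for j, c in enumerate(config.clusters)
        }
    )
    return table, truth


def simulate_survival_cohorts(config: SimCohortConfig):
    """Multi-dataset expression + overall-survival cohorts.

    Signature genes share a latent per-sample score u ~ N(0,1) with loading
    1 and residual sd 0.5; noise genes are independent N(0,1). Event times
    are exponential with hazard proportional to exp(planted_log_hazard * u);
    censoring is an independent exponential calibrated so the expected
    censored fraction equals ``censoring_rate`` under the null.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = list(config.signature_genes) + list(config.noise_genes)
    cohorts = []
    for d in range(config.n_datasets):
        n = config.samples_per_dataset
        u = rng.normal(size=n)
        expr = np.empty((len(genes), n))
        k = len(config.signature_genes)
        expr[:k] = u[None, :] + rng.normal(scale=0.5, size=(k, n))
        expr[k:] = rng.normal(size=(len(config.noise_genes), n))
        sample_ids = [f"D{d}S{i:03d}" for i in range(n)]
        expression = pd.DataFrame(expr, index=genes, columns=sample_ids)

        baseline = 1.0
        t_event = rng.exponential(1.0 / (baseline * np.exp(config.planted_log_hazard * u)))
        c = config.censoring_rate
        if c > 0:
            rate_c = baseline * c / (1.0 - c)
            t_cens = rng.exponential(1.0 / rate_c, size=n)
            event = (t_event <= t_cens).astype(int)
            time = np.minimum(t_event, t_cens)
        else:
            event = np.ones(n, dtype=int)
            time = t_event
        survival = pd.DataFrame({"sample_id": sample_ids, "time": time, "event": event})
        cohorts.append(SurvivalCohort(f"dataset{d}", expression, survival))
    truth = GroundTruth(log_hazard=config.planted_log_hazard)
    return cohorts, truth


def simulate_grouped_measurements(
    group_means: Mapping[str, float],
    n_regions: int = 8,
    cells_per_group_per_region: int = 40,
    region_sd: float = 10.0,
    residual_sd: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Distance-like measurements with a region random intercept.

    value = group mean + region effect + residual; used to calibrate the
    mixed-model contrast machinery against known group effects.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cid = 0
    region_effects = rng.normal(0.0, region_sd, size=n_regions)
    for region in range(n_regions):
        for group, mu in group_means.items():
            vals = mu + region_effects[region] + rng.normal(
                0.0, residual_sd, size=cells_per_group_per_region
            )
            for v in vals:
                cid += 1
                rows.append((cid, region, group, v))
    return pd.DataFrame(rows, columns=["cell_id", "region_id", "group", "distance_um"])
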
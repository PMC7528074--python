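"""Synthetic data generation with known ground truth.

Every input class of the pipeline can be generated here: Yule chronograms,
Brownian-motion traits with tunable phylogenetic signal, environment blocks
with a planted first-singular-pair correlation, specimen-level scale-count
sampling around lineage means, and smooth latitudinal/elevational raster
gradients with per-lineage range masks.

The showcase scenario (:func:`generate_dataset`) emulates the structure of
the real study system: ~39 viper lineages on a ~26 My chronogram, a
mark-count trait (DM analogue) whose variation tracks a deep biogeographic
radiation shared with the ranges' latitudinal positions, and a pigmentation
fraction (WPI analogue) adaptively coupled to the cold end of the realized
environmental gradient over and above phylogeny.  The deep-burst
construction is what makes the DM analogue associate with environment under
naive analyses while being independent of it conditional on the phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .pcm import inv_sqrt_psd, phylo_gls_mean, spawn_seeds
from .rangeenv import (
    DESCRIPTOR_NAMES,
    RangeMask,
    RasterGrid,
    RasterStack,
    range_descriptor_table,
    TEN_ARCMIN,
)
from .traits import TraitError, compute_wpi
from .treeops import Chronogram, PhyloCovariance, phylo_covariance

__all__ = [
    "SyntheticScenario",
    "SyntheticDataset",
    "simulate_yule_tree",
    "simulate_bm_trait",
    "simulate_two_rate_bm",
    "simulate_env_block",
    "simulate_posterior_sample",
    "generate_specimens",
    "generate_raster_stack",
    "generate_dataset",
    "default_loading_pattern",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# scenario


@dataclass
class SyntheticScenario:
    """All knobs of one synthetic study, with study-scale defaults.

    Defaults mirror the real study's conditions: 39 lineages, a ~26 My
    crown age, 1638 specimens of which a fraction 106/1638 lack the zigzag
    pattern, 21 range descriptors, and a planted first-pair correlation of
    0.7 between the pigmentation-fraction trait and the environment.
    """

    seed: int = 0
    # tree
    n_lineages: int = 39
    yule_birth_rate: float = 0.15
    tree_depth_my: float = 26.0
    n_posterior_trees: int = 1000
    posterior_jitter_sd: float = 0.08
    # trait evolution
    bm_sigma2: float = 1.0
    root_state: float = 0.0
    dm_signal_lambda: float = 1.0
    wpi_signal_lambda: float = 0.4
    dm_mean: float = 30.0
    dm_scale: float = 6.0
    wpi_center: float = 0.5
    wpi_scale: float = 0.12
    # trait-environment coupling
    planted_first_pair_r: float = 0.7
    wpi_coupling: str = "residual"
    deep_shared_fraction: float = 0.7
    burst_age_my: float = 24.0
    env_noise_sd: float = 0.4
    # specimen sampling
    n_per_lineage: int = 42
    non_zigzag_fraction: float = 106.0 / 1638.0
    half_scale_fraction: float = 0.2
    dm_specimen_sd: float = 2.0
    n_sample_min: int = 12
    n_sample_max: int = 21
    unassigned_fraction: float = 0.25
    # rasters
    grid_n_rows: int = 72
    origin_lat: float = 30.0
    cell_size: float = TEN_ARCMIN
    mask_height: int = 6
    mask_width: int = 5
    n_small_masks: int = 2
    temp_lat_slope: float = 0.8
    srad_lat_slope: float = 0.9
    prec_lat_slope: float = 25.0
    elev_amplitude: float = 1500.0
    seasonal_amplitude: float = 9.0
    raster_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_lineages < 2:
            raise ValueError("need at least two lineages")
        if not 0 <= self.planted_first_pair_r < 1:
            raise ValueError("planted_first_pair_r must lie in [0, 1)")
        for name in ("non_zigzag_fraction", "half_scale_fraction", "unassigned_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.yule_birth_rate <= 0 or self.tree_depth_my <= 0 or self.bm_sigma2 <= 0:
            raise ValueError("rates and depths must be positive")
        if self.wpi_coupling not in ("residual", "raw"):
            raise ValueError("wpi_coupling must be 'residual' or 'raw'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# trees


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 0.15,
    seed=None,
    depth: float | None = None,
) -> Chronogram:
    """Pure-birth (Yule) chronogram conditioned on ``n_tips``.

    Starts from the crown (two lineages), draws exponential waiting times
    with total rate ``k * birth_rate`` while k lineages are alive, splits a
    uniformly chosen lineage at each event, and extends all pendant edges by
    one final waiting time after the last split.  ``depth`` rescales every
    edge so the crown age is exact.
    """
    if n_tips < 2:
        raise ValueError("a crown tree needs at least two tips")
    rng = _rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node

    start: dict[dendropy.Node, float] = {}
    active: list[dendropy.Node] = []
    t = 0.0
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        start[child] = 0.0
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        node.edge.length = t - start[node]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            start[child] = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.edge.length = t - start[node]

    if depth is not None:
        scale = depth / t
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale

    width = max(2, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(f"v{i:0{width}d}")
    return Chronogram(tree)


def simulate_posterior_sample(
    base: Chronogram, k: int, jitter_sd: float = 0.08, seed=None
) -> list[Chronogram]:
    """Pseudo-posterior around a chronogram: lognormal node-age jitter.

    Internal node ages are perturbed multiplicatively (sd ``jitter_sd`` on
    the log scale), clipped below each node's parent so every draw remains a
    valid ultrametric tree on the fixed topology — a stand-in (synthetic)
    for a Bayesian posterior sample of divergence times.
    """
    rng = _rng(seed)
    out = []
    base_ages = base.node_ages()
    for _ in range(k):
        chrono = base.clone()
        ages = {}
        nodes = list(chrono.tree.preorder_node_iter())
        orig = list(base.tree.preorder_node_iter())
        for node, node0 in zip(nodes, orig):
            if node.is_leaf():
                ages[node] = 0.0
                continue
            a = base_ages[node0] * float(np.exp(rng.normal(0.0, jitter_sd)))
            parent = node.parent_node
            if parent is not None:
                a = min(a, ages[parent] * (1 - 1e-9))
            ages[node] = a
        for node in nodes:
            parent = node.parent_node
            if parent is not None:
                node.edge.length = max(ages[parent] - ages[node], 1e-12)
        out.append(chrono)
    return out


# ---------------------------------------------------------------------------
# trait evolution


def _lambda_cov(C: np.ndarray, signal_lambda: float) -> np.ndarray:
    Cl = signal_lambda * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def simulate_bm_trait(
    tree,
    sigma2: float = 1.0,
    root: float = 0.0,
    signal_lambda: float = 1.0,
    seed=None,
) -> pd.Series:
    """Draw one trait from N(root·1, sigma2·C_lambda).

    ``signal_lambda`` rescales the off-diagonal (shared-path) covariances:
    1 is pure Brownian motion, 0 removes all phylogenetic signal while
    keeping tip variances.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not 0 <= signal_lambda <= 1:
        raise ValueError("signal_lambda must lie in [0, 1]")
    cov = tree if isinstance(tree, PhyloCovariance) else phylo_covariance(tree)
    rng = _rng(seed)
    Cl = _lambda_cov(cov.matrix, signal_lambda)
    L = np.linalg.cholesky(Cl + 1e-12 * np.trace(Cl) / len(cov.labels) * np.eye(len(cov.labels)))
    x = root + np.sqrt(sigma2) * (L @ rng.standard_normal(len(cov.labels)))
    return pd.Series(x, index=cov.labels)


def simulate_two_rate_bm(
    chrono: Chronogram,
    old_rate: float,
    young_rate: float,
    change_age: float,
    seed=None,
    shared_old: np.ndarray | None = None,
) -> tuple[pd.Series, dict]:
    """Brownian trait whose rate switches at ``change_age`` before present.

    Edge segments older than ``change_age`` evolve at variance ``old_rate``
    per My, younger segments at ``young_rate``.  If ``shared_old`` (a per-edge
    increment array from a previous call) is supplied, the old-segment
    increments are reused instead of redrawn — this is how two traits come to
    share only their deep history.  Returns the tip values and a dict with
    the per-edge old increments for reuse.
    """
    rng = _rng(seed)
    ages = chrono.node_ages()
    nodes = [n for n in chrono.tree.preorder_node_iter() if n.parent_node is not None]
    old_spans = np.array(
        [
            max(0.0, ages[n.parent_node] - max(ages[n], change_age))
            for n in nodes
        ]
    )
    young_spans = np.array(
        [
            max(0.0, min(ages[n.parent_node], change_age) - ages[n])
            for n in nodes
        ]
    )
    if shared_old is None:
        old_inc = rng.normal(0.0, 1.0, len(nodes)) * np.sqrt(old_rate * old_spans)
    else:
        old_inc = np.asarray(shared_old, dtype=float)
    young_inc = rng.normal(0.0, 1.0, len(nodes)) * np.sqrt(young_rate * young_spans)

    value: dict[dendropy.Node, float] = {chrono.tree.seed_node: 0.0}
    for node, oi, yi in zip(nodes, old_inc, young_inc):
        value[node] = value[node.parent_node] + oi + yi
    tips = pd.Series(
        {n.taxon.label: value[n] for n in chrono.tree.leaf_node_iter()}
    )
    return tips, {"old_increments": old_inc}


# ---------------------------------------------------------------------------
# environment blocks


def default_loading_pattern() -> pd.Series:
    """Sparse planted loading vector: a cold-climate axis.

    Positive on latitude, negative on minimum solar radiation and minimum
    elevation — the sign structure of a "colder range" direction.  Unit
    norm; the largest-magnitude entry (LATmax) is positive, so the fixed
    sign convention of the PLS loadings leaves the pattern unflipped.
    """
    w = pd.Series(0.0, index=DESCRIPTOR_NAMES)
    w["LATmax"] = 0.55
    w["LATavg"] = 0.35
    w["SRADmin"] = -0.50
    w["ELEVmin"] = -0.45
    w["SRADavg"] = -0.20
    w["ELEVmax"] = 0.25
    return w / np.linalg.norm(w)


#: additive per-descriptor offsets giving each family a realistic location
#: and the min <= avg <= max ordering (offsets do not affect any analysis,
#: which centers every column)
_FAMILY_OFFSETS = {
    "PRECmax": 900.0, "PRECmin": 880.0,
    "SRADavg": 14.0, "SRADmax": 17.0, "SRADmin": 11.0,
    "TAVGavg": 10.0, "TAVGmax": 18.0, "TAVGmin": 2.0,
    "TMAXmax": 24.0, "TMAXmin": 8.0,
    "TMINmax": 12.0, "TMINmin": -4.0,
    "VPRavg": 1.2, "VPRmax": 1.9, "VPRmin": 0.5,
    "ELEVavg": 800.0, "ELEVmax": 1600.0, "ELEVmin": 150.0,
    "LATavg": 41.0, "LATmax": 45.0, "LATmin": 37.0,
}


def simulate_env_block(
    trait,
    C=None,
    planted_r: float = 0.7,
    loading_pattern: pd.Series | None = None,
    noise_sd: float = 0.4,
    coupling: str = "residual",
    seed=None,
) -> pd.DataFrame:
    """Environment block with a planted first-singular-pair correlation.

    The latent environmental axis correlates exactly ``planted_r`` with the
    trait — with its phylogenetic residuals (``coupling='residual'``, the
    default; requires ``C``, and the block is mapped back through C^{1/2} so
    the planted structure lives where phylogenetic PLS looks for it), with
    the raw centered values (``coupling='raw'``), or with an independent
    Brownian trait on the same tree (``coupling='shared_history'``, in which
    case any trait-environment association is purely phylogenetic).
    Descriptor columns are the planted axis times the loading pattern plus
    iid noise, shifted by family offsets.
    """
    if not 0 <= planted_r < 1:
        raise ValueError("planted_r must lie in [0, 1)")
    rng = _rng(seed)
    if isinstance(trait, pd.Series):
        labels = [str(i) for i in trait.index]
        x = trait.to_numpy(dtype=float)
    else:
        x = np.asarray(trait, dtype=float)
        labels = [f"v{i + 1:02d}" for i in range(x.size)]
    n = x.size
    w = loading_pattern if loading_pattern is not None else default_loading_pattern()
    w = w.reindex(DESCRIPTOR_NAMES).fillna(0.0)
    w = w / np.linalg.norm(w)

    Cm = None
    if C is not None:
        Cm = C.reorder(labels).matrix if isinstance(C, PhyloCovariance) else np.asarray(C)

    if coupling == "residual":
        if Cm is not None:
            P = inv_sqrt_psd(Cm)
            z = _standardize(P @ (x - phylo_gls_mean(x, Cm)))
        else:
            z = _standardize(x)
    elif coupling == "raw":
        z = _standardize(x)
    elif coupling == "shared_history":
        if Cm is None:
            raise ValueError("shared_history coupling requires the covariance C")
        L = np.linalg.cholesky(Cm + 1e-10 * np.trace(Cm) / n * np.eye(n))
        z = _standardize(L @ rng.standard_normal(n))
    else:
        raise ValueError(f"unknown coupling mode {coupling!r}")

    g = rng.standard_normal(n)
    g = g - z * (z @ g) / (z @ z)  # exact orthogonality -> exact planted r
    g = _standardize(g)
    axis = planted_r * z + np.sqrt(1.0 - planted_r**2) * g

    # nuisance variation is low-rank (climate descriptors are collinear):
    # four shared factors per block plus a little independent noise
    n_factors = 4
    G = rng.standard_normal((n, n_factors))
    B = rng.standard_normal((n_factors, len(DESCRIPTOR_NAMES)))
    B /= np.linalg.norm(B, axis=0)
    block = (
        np.outer(axis, w.to_numpy())
        + 0.9 * noise_sd * (G @ B)
        + 0.45 * noise_sd * rng.standard_normal((n, len(DESCRIPTOR_NAMES)))
    )
    if coupling == "residual" and Cm is not None:
        # place the structure in whitened space: de-whiten with C^{1/2}
        lam, U = np.linalg.eigh(Cm)
        half = (U * np.sqrt(np.clip(lam, 0, None))) @ U.T
        block = half @ block / np.sqrt(np.mean(np.diag(Cm)))
    offsets = np.array([_FAMILY_OFFSETS[name] for name in DESCRIPTOR_NAMES])
    return pd.DataFrame(
        block + offsets, index=labels, columns=DESCRIPTOR_NAMES
    )


# ---------------------------------------------------------------------------
# specimens


def generate_specimens(
    lineage_means: pd.DataFrame,
    n_per_lineage: int = 42,
    half_scale_fraction: float = 0.2,
    non_zigzag_fraction: float = 106.0 / 1638.0,
    dm_specimen_sd: float = 2.0,
    n_sample_min: int = 12,
    n_sample_max: int = 21,
    masks=None,
    grid=None,
    unassigned_fraction: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Specimen-level records around lineage trait means.

    Scale states in the sampling rectangle are drawn per scale from a
    three-outcome distribution (fully pigmented, half pigmented, background)
    with probabilities ``(wpi - h/2, h, 1 - wpi - h/2)`` for half-fraction
    ``h``, so the expected specimen WPI equals the lineage mean.  DM is a
    rounded Gaussian around the lineage mean; body sizes are lognormal; a
    ``non_zigzag_fraction`` of records get a non-zigzag pattern class.  With
    ``masks``/``grid``, coordinates are drawn inside the lineage's range and
    an ``unassigned_fraction`` of records have their lineage_id blanked so
    the coordinate-assignment path is exercised.
    """
    rng = _rng(seed)
    h = half_scale_fraction
    records = []
    others = np.array(["melanistic", "striped", "uniform"])
    for _, row in lineage_means.iterrows():
        lid = str(row["lineage_id"])
        wpi, dm_mean = float(row["wpi"]), float(row["dm"])
        if wpi - h / 2 < 0 or 1 - wpi - h / 2 < 0:
            raise TraitError(
                f"infeasible (wpi={wpi:.3f}, half_fraction={h}) for {lid}: "
                "scale-state probabilities would be negative"
            )
        n_sample = int(
            row["n_sample"]
            if "n_sample" in row and not pd.isna(row.get("n_sample"))
            else rng.integers(n_sample_min, n_sample_max + 1)
        )
        total = 10 * n_sample
        probs = [wpi - h / 2, h, 1 - wpi - h / 2]
        counts = rng.multinomial(total, probs, size=n_per_lineage)
        dm = np.maximum(
            np.rint(rng.normal(dm_mean, dm_specimen_sd, n_per_lineage)), 0
        ).astype(int)
        sizes = np.round(rng.lognormal(np.log(550.0), 0.22, n_per_lineage), 1)
        non_zig = rng.random(n_per_lineage) < non_zigzag_fraction
        patterns = np.where(
            non_zig, others[rng.integers(0, 3, n_per_lineage)], "zigzag"
        )
        lons = np.full(n_per_lineage, np.nan)
        lats = np.full(n_per_lineage, np.nan)
        if masks is not None and grid is not None:
            cells = sorted(masks[lid].cells)
            picks = rng.integers(0, len(cells), n_per_lineage)
            jitter = rng.random((n_per_lineage, 2))
            for j, pick in enumerate(picks):
                r, c = cells[pick]
                lons[j] = grid.origin_lon + (c + jitter[j, 0]) * grid.cell_size
                lats[j] = grid.origin_lat + (r + jitter[j, 1]) * grid.cell_size
        blank = (
            rng.random(n_per_lineage) < unassigned_fraction
            if masks is not None
            else np.zeros(n_per_lineage, bool)
        )
        for j in range(n_per_lineage):
            records.append(
                {
                    "specimen_id": f"{lid}_s{j + 1:03d}",
                    "lineage_id": "" if blank[j] else lid,
                    "lon": lons[j],
                    "lat": lats[j],
                    "body_size_mm": sizes[j],
                    "pattern": patterns[j],
                    "dm": int(dm[j]),
                    "rect_des": int(counts[j, 0]),
                    "rect_half": int(counts[j, 1]),
                    "n_sample": n_sample,
                }
            )
    df = pd.DataFrame.from_records(records)
    df["wpi"] = compute_wpi(
        df["rect_des"].to_numpy(), df["rect_half"].to_numpy(), df["n_sample"].to_numpy()
    )
    return df


# ---------------------------------------------------------------------------
# rasters


def generate_raster_stack(
    scenario: SyntheticScenario,
    row_centers: pd.Series,
    seed=None,
) -> tuple[RasterStack, dict[str, RangeMask]]:
    """Monthly climate rasters with latitudinal gradients plus range masks.

    Temperature and vapour pressure fall with latitude and elevation, solar
    radiation falls with latitude, precipitation rises with it; monthly
    layers follow a sinusoidal seasonal cycle.  Each lineage's mask is a
    rectangle in an exclusive longitude band (so ranges never overlap),
    vertically centred on ``row_centers[lineage]``; the first
    ``n_small_masks`` lineages get sub-20-cell ranges to exercise the
    small-range trimming exemption.
    """
    rng = _rng(seed)
    sc = scenario
    lineages = list(row_centers.index)
    n_rows = sc.grid_n_rows
    n_cols = sc.mask_width * len(lineages)
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    grid_kw = dict(origin_lon=0.0, origin_lat=sc.origin_lat, cell_size=sc.cell_size)

    lat = sc.origin_lat + (rows + 0.5) * sc.cell_size + 0.0 * cols
    lat0 = sc.origin_lat + 0.5 * n_rows * sc.cell_size
    elev = (
        sc.elev_amplitude
        * 0.5
        * (1.0 + np.sin(2 * np.pi * cols / 23.0) * np.cos(2 * np.pi * rows / 31.0))
    )

    def noisy(base: np.ndarray, scale: float) -> np.ndarray:
        return base + scale * rng.standard_normal(base.shape)

    monthly: dict[str, list[RasterGrid]] = {v: [] for v in ("tavg", "tmax", "tmin", "prec", "srad", "vpr")}
    for m in range(1, 13):
        season = np.cos(2 * np.pi * (m - 7) / 12.0)
        tavg = (
            12.0
            - sc.temp_lat_slope * (lat - lat0)
            - 6.5 * elev / 1000.0
            + sc.seasonal_amplitude * season
        )
        monthly["tavg"].append(RasterGrid(noisy(tavg, sc.raster_noise_sd), **grid_kw))
        monthly["tmax"].append(RasterGrid(noisy(tavg + 7.0, sc.raster_noise_sd), **grid_kw))
        monthly["tmin"].append(RasterGrid(noisy(tavg - 7.0, sc.raster_noise_sd), **grid_kw))
        srad = np.maximum(
            14.0 - sc.srad_lat_slope * (lat - lat0) + 6.0 * season, 0.5
        )
        monthly["srad"].append(RasterGrid(noisy(srad, sc.raster_noise_sd), **grid_kw))
        prec = np.maximum(
            70.0 + sc.prec_lat_slope * (lat - lat0) / 6.0 - 25.0 * season, 0.0
        )
        monthly["prec"].append(RasterGrid(noisy(prec, 2.0 * sc.raster_noise_sd), **grid_kw))
        vpr = np.maximum(1.0 + 0.04 * tavg, 0.05)
        monthly["vpr"].append(RasterGrid(noisy(vpr, 0.05 * sc.raster_noise_sd), **grid_kw))
    stack = RasterStack(monthly, RasterGrid(elev, **grid_kw))

    masks: dict[str, RangeMask] = {}
    for i, lid in enumerate(lineages):
        if i < sc.n_small_masks:
            height, width = 3, 3
        else:
            height, width = sc.mask_height, sc.mask_width
        r0 = int(np.clip(round(row_centers[lid] - height / 2), 0, n_rows - height))
        c0 = i * sc.mask_width
        cells = frozenset(
            (r, c)
            for r in range(r0, r0 + height)
            for c in range(c0, c0 + width)
        )
        masks[lid] = RangeMask(lid, cells)
    return stack, masks


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class SyntheticDataset:
    """A complete synthetic study with its ground truth."""

    scenario: SyntheticScenario
    tree: Chronogram
    posterior: list[Chronogram]
    specimens: pd.DataFrame
    stack: RasterStack
    masks: dict[str, RangeMask]
    truth: dict = field(default_factory=dict)

    def write_dir(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.scenario.to_yaml(directory / "scenario.yml")
        from .treeops import write_trees

        write_trees([self.tree], directory / "tree.nwk", schema="newick")
        write_trees(self.posterior, directory / "posterior.nex", schema="nexus")
        self.specimens.drop(columns=["wpi"], errors="ignore").to_csv(
            directory / "specimens.csv", index=False
        )
        self.stack.write_dir(directory / "rasters")
        from .rangeenv import write_masks_csv

        write_masks_csv(self.masks, self.stack.grid, directory / "masks.csv")
        self.truth["lineage_means"].to_csv(directory / "truth_lineage_means.csv", index=False)


def generate_dataset(scenario: SyntheticScenario) -> SyntheticDataset:
    """Generate the full showcase dataset for a scenario.

    Construction order: chronogram, deep-burst biogeographic axis (shared by
    range latitudes and the DM analogue), rasters and masks, realized
    descriptor table, WPI analogue coupled to the realized cold axis, and
    finally specimen-level sampling.
    """
    sc = scenario
    seeds = spawn_seeds(sc.seed, 8)
    tree = simulate_yule_tree(
        sc.n_lineages, sc.yule_birth_rate, seed=np.random.default_rng(seeds[0]),
        depth=sc.tree_depth_my,
    )
    cov = phylo_covariance(tree)
    labels = cov.labels

    # deep-burst shared axis: the DM analogue and the biogeographic (range
    # latitude) axis share only the standardized pattern of Brownian
    # increments accumulated before burst_age_my (the early radiation into
    # different regions); their recent evolution is independent.  Components
    # are standardized and orthogonalized so the realized shared-variance
    # fraction equals deep_shared_fraction exactly.
    f = sc.deep_shared_fraction
    rng_deep = np.random.default_rng(seeds[1])
    deep, _ = simulate_two_rate_bm(
        tree, sc.bm_sigma2, 0.0, sc.burst_age_my, seed=rng_deep
    )
    z_s = _standardize(deep[labels].to_numpy())

    def _young_component(rng) -> np.ndarray:
        y, _ = simulate_two_rate_bm(tree, 0.0, sc.bm_sigma2, sc.burst_age_my, seed=rng)
        y = y[labels].to_numpy()
        return _standardize(y - z_s * (z_s @ y) / (z_s @ z_s))

    dm_latent = np.sqrt(f) * z_s + np.sqrt(1 - f) * _young_component(rng_deep)
    region = np.sqrt(f) * z_s + np.sqrt(1 - f) * _young_component(rng_deep)
    region = pd.Series(region, index=labels)
    dm_latent = pd.Series(dm_latent, index=labels)
    dm_means = sc.dm_mean + sc.dm_scale * _standardize(dm_latent.to_numpy())

    # ranges occupy latitude bands in rank order of the biogeographic axis
    from scipy.stats import rankdata

    margin = sc.mask_height
    ranks = rankdata(region.to_numpy())
    rows = margin + (sc.grid_n_rows - 2 * margin) * (ranks - 0.5) / len(ranks)
    row_centers = pd.Series(rows, index=labels)
    stack, masks = generate_raster_stack(
        sc, row_centers, seed=np.random.default_rng(seeds[2])
    )
    descriptors = range_descriptor_table(stack, masks).loc[labels]

    # WPI analogue: coupled to the realized cold axis beyond phylogeny
    rng_wpi = np.random.default_rng(seeds[3])
    cold = descriptors["LATavg"].to_numpy()
    r = sc.planted_first_pair_r
    if sc.wpi_coupling == "residual":
        P = inv_sqrt_psd(cov.matrix)
        zc = _standardize(P @ (cold - phylo_gls_mean(cold, cov.matrix)))
    else:
        zc = _standardize(cold)
    noise = simulate_bm_trait(
        cov, sigma2=sc.bm_sigma2, signal_lambda=sc.wpi_signal_lambda, seed=rng_wpi
    ).to_numpy()
    if sc.wpi_coupling == "residual":
        zn = _standardize(P @ (noise - noise.mean()))
    else:
        zn = _standardize(noise)
    zn = _standardize(zn - zc * (zc @ zn) / (zc @ zc))
    wpi_whitened = r * zc + np.sqrt(1 - r**2) * zn
    if sc.wpi_coupling == "residual":
        lam, U = np.linalg.eigh(cov.matrix)
        half = (U * np.sqrt(np.clip(lam, 0, None))) @ U.T
        wpi_latent = half @ wpi_whitened / np.sqrt(np.mean(np.diag(cov.matrix)))
    else:
        wpi_latent = wpi_whitened
    wpi_means = np.clip(
        sc.wpi_center + sc.wpi_scale * _standardize(wpi_latent),
        sc.half_scale_fraction / 2 + 0.01,
        1 - sc.half_scale_fraction / 2 - 0.01,
    )

    lineage_means = pd.DataFrame(
        {"lineage_id": labels, "dm": dm_means, "wpi": wpi_means}
    )
    specimens = generate_specimens(
        lineage_means,
        n_per_lineage=sc.n_per_lineage,
        half_scale_fraction=sc.half_scale_fraction,
        non_zigzag_fraction=sc.non_zigzag_fraction,
        dm_specimen_sd=sc.dm_specimen_sd,
        n_sample_min=sc.n_sample_min,
        n_sample_max=sc.n_sample_max,
        masks=masks,
        grid=stack.grid,
        unassigned_fraction=sc.unassigned_fraction,
        seed=np.random.default_rng(seeds[4]),
    )
    posterior = simulate_posterior_sample(
        tree, sc.n_posterior_trees, sc.posterior_jitter_sd,
        seed=np.random.default_rng(seeds[5]),
    )
    truth = {
        "lineage_means": lineage_means,
        "region_axis": region,
        "dm_latent": dm_latent,
        "cold_axis": pd.Series(cold, index=labels),
        "descriptors": descriptors,
        "planted_r": r,
    }
    return SyntheticDataset(sc, tree, posterior, specimens, stack, masks, truth)
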
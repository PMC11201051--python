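"""Seeded synthetic landscapes, virtual species, and climate scenarios.

Real occurrence and climate layers for the study species are not
redistributable, so every pipeline stage is exercised on synthetic
inputs with known ground truth: smooth spatially autocorrelated
environmental fields (sums of random Gaussian bumps plus a latitudinal
gradient), a virtual species whose suitability is a logistic of a
quadratic form in a few chosen variables (unimodal response per
variable, like real single-factor response curves), redundant layers
built at a target correlation with a base layer, and "future" scenarios
made by adding exact offsets to chosen variables.

The default extent is a 50×50 grid of 0.05° cells over lon [100, 102.5],
lat [30, 32.5] — mid-latitude so spherical area weighting is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_io import EnvGrid, GridHeader, GridStack, align_stack
from .occurrence import OccurrenceSet

DEFAULT_N_BUMPS = 10
MAX_MUTUAL_R = 0.3   # target mutual independence of generated layers


def default_header(n: int = 50, cellsize: float = 0.05,
                   xll: float = 100.0, yll: float = 30.0) -> GridHeader:
    return GridHeader(ncols=n, nrows=n, xllcorner=xll, yllcorner=yll,
                      cellsize=cellsize)


def _smooth_field(header: GridHeader, rng: np.random.Generator,
                  n_bumps: int, gradient: float) -> np.ndarray:
    """One standardised smooth field: Gaussian bumps + latitude gradient."""
    lon = header.col_centers()
    lat = header.row_centers()
    LON, LAT = np.meshgrid(lon, lat)
    width_lon = header.ncols * header.cellsize
    width_lat = header.nrows * header.cellsize
    z = np.zeros_like(LON)
    for _ in range(n_bumps):
        cx = header.xllcorner + rng.uniform(0, width_lon)
        cy = header.yllcorner + rng.uniform(0, width_lat)
        sx = rng.uniform(0.1, 0.35) * width_lon
        sy = rng.uniform(0.1, 0.35) * width_lat
        amp = rng.normal(0.0, 1.0)
        z += amp * np.exp(-(((LON - cx) / sx) ** 2 + ((LAT - cy) / sy) ** 2))
    z += gradient * rng.normal(0.0, 1.0) * (LAT - LAT.mean()) / max(LAT.std(), 1e-12)
    sd = z.std()
    if sd == 0:  # degenerate 1×1 grids: keep the raw value
        return z
    return (z - z.mean()) / sd


def make_env_stack(n_vars: int, header: GridHeader | None = None,
                   seed: int = 0, n_bumps: int = DEFAULT_N_BUMPS,
                   gradient: float = 0.5, names: list[str] | None = None,
                   max_retries: int = 200) -> GridStack:
    """Generate mutually near-independent standardised layers.

    Layers are resampled (deterministically, from the same seed stream)
    until every pair satisfies |r| < 0.3 over the grid, so downstream
    collinearity in tests comes only from deliberately constructed
    redundant layers.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be at least 1")
    header = header or default_header()
    rng = np.random.default_rng(seed)
    names = names or [f"env{i + 1:02d}" for i in range(n_vars)]
    fields: list[np.ndarray] = []
    for i in range(n_vars):
        for _ in range(max_retries):
            z = _smooth_field(header, rng, n_bumps, gradient)
            if header.ncols * header.nrows < 9:
                break
            ok = all(abs(np.corrcoef(z.ravel(), prev.ravel())[0, 1]) < MAX_MUTUAL_R
                     for prev in fields)
            if ok:
                break
        fields.append(z)
    grids = [EnvGrid(header, names[i], fields[i]) for i in range(n_vars)]
    return align_stack(grids)


def make_correlated_variable(base: EnvGrid, target_r: float, seed: int = 0,
                             name: str | None = None,
                             n_bumps: int = DEFAULT_N_BUMPS) -> EnvGrid:
    """New layer correlated with ``base`` at approximately ``target_r``.

    Constructed as r·standardised(base) + sqrt(1−r²)·standardised(noise)
    with a smooth noise field, so redundant layers look like climate
    layers rather than white noise.
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target_r must lie in [-1, 1]")
    vals = base.values
    valid = ~np.isnan(vals)
    sd = np.nanstd(vals)
    if sd == 0:
        raise ValueError(f"base layer '{base.name}' is constant")
    zb = (vals - np.nanmean(vals)) / sd
    rng = np.random.default_rng(seed)
    noise = _smooth_field(base.header, rng, n_bumps, gradient=0.5)
    # orthogonalise the noise against the base so sample r tracks target_r
    nb = noise[valid] - np.mean(noise[valid])
    zbv = zb[valid]
    nb = nb - (nb @ zbv) / (zbv @ zbv) * zbv
    nsd = nb.std()
    out = np.full_like(vals, np.nan)
    out[valid] = target_r * zbv + (np.sqrt(max(0.0, 1.0 - target_r ** 2))
                                   * (nb / nsd if nsd > 0 else nb))
    return EnvGrid(base.header, name or f"{base.name}_r{target_r:g}", out)


@dataclass
class SyntheticNiche:
    """Virtual species: logistic of a quadratic form in selected variables.

    suitability(x) = σ( intercept − Σ_v ((x_v − optimum_v) / breadth_v)² )

    The response to each selected variable is unimodal with its maximum
    at ``optimum_v``; the intercept is calibrated so the grid-mean true
    suitability hits a target prevalence.
    """

    variables: list[str]
    optima: dict[str, float]
    breadths: dict[str, float]
    intercept: float = 0.0

    def suitability_table(self, table: pd.DataFrame) -> np.ndarray:
        z = np.full(len(table), self.intercept, dtype=float)
        for v in self.variables:
            z -= ((table[v].to_numpy(dtype=float) - self.optima[v])
                  / self.breadths[v]) ** 2
        return 1.0 / (1.0 + np.exp(-z))

    def true_suitability(self, stack: GridStack) -> EnvGrid:
        table = stack.to_table()
        p = self.suitability_table(table)
        header = stack.header
        out = np.full((header.nrows, header.ncols), np.nan)
        out[table["row"].to_numpy(), table["col"].to_numpy()] = p
        return EnvGrid(header, "true_suitability", out)


def make_niche(stack: GridStack, variables: list[str], seed: int = 0,
               prevalence: float = 0.05,
               breadth_sd: tuple[float, float] = (0.4, 0.8)) -> SyntheticNiche:
    """Draw a niche with optima inside each variable's generated range.

    Optima land between the 35th and 65th percentile of the layer so
    the peak is interior; breadths are drawn in units of the layer s.d.;
    the intercept is calibrated by bisection to the target prevalence.
    """
    rng = np.random.default_rng(seed)
    table = stack.to_table()
    optima, breadths = {}, {}
    for v in variables:
        col = table[v].to_numpy(dtype=float)
        q = rng.uniform(0.35, 0.65)
        optima[v] = float(np.quantile(col, q))
        breadths[v] = float(rng.uniform(*breadth_sd) * col.std())
    niche = SyntheticNiche(variables, optima, breadths)
    lo, hi = -30.0, 30.0
    for _ in range(80):
        niche.intercept = (lo + hi) / 2.0
        mean_p = float(niche.suitability_table(table).mean())
        if mean_p > prevalence:
            hi = niche.intercept
        else:
            lo = niche.intercept
    return niche


def sample_occurrences(true_suitability: EnvGrid, n: int, seed: int = 0,
                       species: str = "virtual") -> OccurrenceSet:
    """Draw presences with probability proportional to true suitability.

    Cells are sampled with replacement; each draw becomes a point
    uniformly jittered within its cell (exact duplicates are collapsed
    downstream by the cleaning flow, mirroring real ingestion).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    v = true_suitability.values
    valid = ~np.isnan(v)
    weights = np.where(valid, v, 0.0).ravel()
    total = weights.sum()
    if total <= 0:
        raise ValueError("true suitability is zero everywhere")
    rng = np.random.default_rng(seed)
    flat = rng.choice(v.size, size=n, replace=True, p=weights / total)
    rows, cols = np.unravel_index(flat, v.shape)
    header = true_suitability.header
    lon = header.xllcorner + (cols + rng.uniform(0, 1, n)) * header.cellsize
    lat = header.yllcorner + (header.nrows - rows - rng.uniform(0, 1, n)) \
        * header.cellsize
    df = pd.DataFrame({"species": species, "longitude": lon, "latitude": lat,
                       "source": "synthetic"})
    return OccurrenceSet(df)


@dataclass
class ScenarioSeries:
    """'current' plus shifted stacks emulating climate scenarios.

    Shifts are exact additive offsets per variable; with a fixed niche
    the suitable region moves toward cells whose shifted values sit at
    the optimum, giving an analytically known migration direction.
    """

    stacks: dict[str, GridStack]
    shifts: dict[str, dict[str, float]]

    @property
    def names(self) -> list[str]:
        return list(self.stacks.keys())


def make_scenario_series(stack: GridStack,
                         shifts: dict[str, dict[str, float]],
                         baseline_name: str = "current") -> ScenarioSeries:
    """Apply exact additive shifts to chosen variables per scenario."""
    stacks: dict[str, GridStack] = {baseline_name: stack}
    recorded: dict[str, dict[str, float]] = {baseline_name: {}}
    for scenario, offsets in shifts.items():
        missing = [v for v in offsets if v not in stack.layers]
        if missing:
            raise KeyError(f"scenario '{scenario}' shifts unknown variables "
                           f"{missing}")
        layers = []
        for name, g in stack.layers.items():
            delta = offsets.get(name, 0.0)
            layers.append(g.with_values(g.values + delta) if delta
                          else g.with_values(g.values.copy()))
        stacks[scenario] = align_stack(layers)
        recorded[scenario] = dict(offsets)
    return ScenarioSeries(stacks, recorded)


# ---------------------------------------------------------------------------
# the full synthetic study design


@dataclass
class SyntheticStudy:
    """A complete generated study: layers, niche, occurrences, scenarios."""

    series: ScenarioSeries
    niche: SyntheticNiche
    occurrences: OccurrenceSet
    informative: list[str]
    redundant: dict[str, str]   # redundant layer -> its base layer
    noise: list[str]

    @property
    def stack(self) -> GridStack:
        return self.series.stacks["current"]


def make_study(n_base: int = 8, n_niche: int = 4, n_redundant: int = 26,
               n_noise: int = 2, n_occurrences: int = 894,
               redundant_r: float = 0.98, prevalence: float = 0.05,
               header: GridHeader | None = None, seed: int = 0,
               shift_sd: float = 0.5,
               scenario_names: tuple[str, ...] = ("future",)) -> SyntheticStudy:
    """Generate the study-design landscape used across the test battery.

    Defaults follow the candidate-set structure of the source study: 36
    layers total — 8 mutually near-independent informative bases (the
    virtual species responds to ``n_niche`` of them), 26 redundant
    variants correlated with the bases at ≈ 0.98 (near-duplicates, as collinear bioclim siblings are), and 2 independent
    noise layers — with 894 occurrence draws.  Scenarios add
    ``shift_sd`` (layer s.d. units) to the first niche variable.
    """
    header = header or default_header()
    rng = np.random.default_rng(seed)
    base = make_env_stack(n_base, header, seed=int(rng.integers(2 ** 31)),
                          names=[f"base{i + 1:02d}" for i in range(n_base)])
    layers = list(base.layers.values())
    informative = base.names[:n_niche]
    redundant: dict[str, str] = {}
    for i in range(n_redundant):
        parent = layers[i % n_base]
        name = f"red{i + 1:02d}_{parent.name}"
        layers.append(make_correlated_variable(
            parent, redundant_r, seed=int(rng.integers(2 ** 31)), name=name))
        redundant[name] = parent.name
    noise_names = []
    for i in range(n_noise):
        g = make_env_stack(1, header, seed=int(rng.integers(2 ** 31)),
                           names=[f"noise{i + 1:02d}"])
        layers.append(next(iter(g.layers.values())))
        noise_names.append(f"noise{i + 1:02d}")
    stack = align_stack(layers)
    niche = make_niche(stack, informative, seed=int(rng.integers(2 ** 31)),
                       prevalence=prevalence)
    occ = sample_occurrences(niche.true_suitability(stack), n_occurrences,
                             seed=int(rng.integers(2 ** 31)))
    shift_var = informative[0]
    sd = float(np.nanstd(stack.layers[shift_var].values))
    shifts = {name: {shift_var: (i + 1) * shift_sd * sd}
              for i, name in enumerate(scenario_names)}
    series = make_scenario_series(stack, shifts)
    return SyntheticStudy(series=series, niche=niche, occurrences=occ,
                          informative=informative, redundant=redundant,
                          noise=noise_names)
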
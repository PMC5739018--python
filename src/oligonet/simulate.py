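"""Synthetic two-year seasonal community generator with planted modules.

Emulates the statistical structure that the downstream network pipeline
assumes: a weekly-sampled coastal time series over two years, driven by a
sinusoidal temperature cycle, spring/summer chlorophyll pulses and
winter-high inorganic nutrients; guilds ("modules") of taxa co-vary because
they load on a shared environmental driver; counts are compositional
(multinomial draws from closed relative abundances), so naive correlations
on the counts are distorted exactly the way real amplicon data are.

The generative model per taxon i and sample t is a latent log-abundance

    lambda_it = b_i + l_i * g_{m(i)}(t) + e_it,

where g_m is the z-scored driver series of taxon i's module m (background
taxa have l_i = 0), e_it is stationary AR(1) noise, relative abundances are
the softmax of lambda over taxa (closure), and counts are
Multinomial(depth, p_t).  Baselines b and loadings l are shared between the
two years, except for an optional ``perturb_module`` whose year-2 loadings
are re-drawn from a symmetric-about-zero range — a guild whose internal
correlation structure is poorly conserved across years.

A read simulator is also provided so the entropy-decomposition stage has a
fixture with known template-of-origin for every read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .med import AlignedReadSet
from .tables import OligotypeTable, sample_id

DAYS_PER_YEAR = 365
_DRIVER_COLUMNS = {"temperature": "temperature", "chl_a": "chl_a",
                   "nutrient": "DIN", "salinity": "salinity"}

#: default driver per planted module (1-based module labels; 0 = background)
DEFAULT_DRIVERS = {1: "temperature", 2: "chl_a", 3: "nutrient", 4: "salinity"}


@dataclass
class CommunitySimSpec:
    """Parameters of the two-year community simulation.

    Defaults describe the desk-scale study conditions: 200 taxa of which
    four modules of 40 co-vary with distinct seasonal drivers and 40 form a
    low-abundance background pool, 50 weekly samples per year at 5,000 reads
    per sample.
    """

    n_taxa: int = 200
    n_modules: int = 4
    samples_per_year: int = 50
    depth: int = 5000
    module_driver_map: dict = field(default_factory=lambda: dict(DEFAULT_DRIVERS))
    loading_range: tuple = (0.75, 1.25)
    ar1_rho: float = 0.5
    noise_sd: float = 0.3
    background_frac: float = 0.2
    perturb_module: int | None = None
    depth_cv: float = 0.0          # lognormal CV of per-sample depth; 0 = constant
    seed: int = 0

    # environmental driver shapes (units: degC, ug/l, arbitrary nutrient units)
    temp_mean: float = 10.0
    temp_amplitude: float = 6.0
    temp_phase: float = 109.0      # sine phase; peak near day 200
    chl_baseline: float = 0.5
    chl_pulses: tuple = ((125.0, 8.0, 18.0), (215.0, 5.0, 25.0))  # (day, amp, width)
    env_noise_sd: float = 0.05     # relative to each variable's amplitude

    def __post_init__(self):
        if self.n_modules < 2:
            raise ValueError("n_modules must be >= 2")
        if self.samples_per_year < 10:
            raise ValueError("samples_per_year must be >= 10")
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for m in range(1, self.n_modules + 1):
            if m not in self.module_driver_map:
                raise ValueError(f"module {m} missing from module_driver_map")

    @property
    def sample_days(self) -> np.ndarray:
        """Weekly grid: every 7 days starting at day 4."""
        days = 4 + 7 * np.arange(self.samples_per_year)
        if days[-1] > DAYS_PER_YEAR:
            raise ValueError("weekly grid exceeds 365 days")
        return days


def _gaussian_pulse(day, centre, amp, width):
    return amp * np.exp(-0.5 * ((day - centre) / width) ** 2)


def generate_env(spec: CommunitySimSpec) -> pd.DataFrame:
    """Two-year environmental table on the weekly sampling grid.

    Columns: ``year``, ``day``, ``temperature``, ``chl_a``, ``SiO2``,
    ``PO4``, ``DIN``, ``salinity``.  Temperature is a sinusoid, chl a is a
    baseline plus spring/summer Gaussian pulses, inorganic nutrients are
    winter-high sinusoids depleted proportionally to chl a (floored at 0),
    and salinity is a weak sinusoid.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([spec.seed, 0])
    days = spec.sample_days
    rows = []
    index = []
    for year in (1, 2):
        d = days.astype(float)
        omega = 2 * np.pi / DAYS_PER_YEAR
        temp = spec.temp_mean + spec.temp_amplitude * np.sin(omega * (d - spec.temp_phase))
        chl = np.full_like(d, spec.chl_baseline)
        for centre, amp, width in spec.chl_pulses:
            chl = chl + _gaussian_pulse(d, centre, amp, width)
        # winter-high nutrient sinusoids, depleted by the bloom, floored at 0;
        # phases and bloom-coupling differ per species (differential uptake
        # and remineralisation) so the nutrients correlate without being
        # collinear
        din = 9.0 + 6.0 * np.sin(omega * (d - 288.75)) - 0.5 * chl
        sio2 = 12.0 + 7.0 * np.sin(omega * (d - 333.75)) - 1.1 * chl
        po4 = 0.8 + 0.45 * np.sin(omega * (d - 248.75)) - 0.01 * chl
        sal = 32.0 + 0.8 * np.sin(omega * (d - 353.75))

        chl_amp = max((a for _, a, _ in spec.chl_pulses), default=1.0)
        scales = {
            "temperature": (temp, spec.temp_amplitude, False),
            "chl_a": (chl, chl_amp, True),
            "SiO2": (sio2, 7.0, True),
            "PO4": (po4, 0.45, True),
            "DIN": (din, 6.0, True),
            "salinity": (sal, 0.8, False),
        }
        cols = {}
        for name, (series, amp, floored) in scales.items():
            noisy = series + rng.normal(0.0, spec.env_noise_sd * amp, size=d.shape)
            cols[name] = np.maximum(noisy, 0.0) if floored else noisy
        for k, day in enumerate(days):
            rows.append(
                [year, int(day)] + [cols[name][k] for name in scales]
            )
            index.append(sample_id(year, int(day)))
    env = pd.DataFrame(
        rows,
        index=index,
        columns=["year", "day", "temperature", "chl_a", "SiO2", "PO4", "DIN", "salinity"],
    )
    env["year"] = env["year"].astype(int)
    env["day"] = env["day"].astype(int)
    return env


def _driver_series(env: pd.DataFrame, driver: str) -> np.ndarray:
    """Signed, z-scored driver series over both years."""
    sign = 1.0
    name = driver
    if driver.startswith("-"):
        sign, name = -1.0, driver[1:]
    col = _DRIVER_COLUMNS.get(name, name)
    if col not in env.columns:
        raise KeyError(f"unknown driver {driver!r}")
    x = env[col].to_numpy(dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return sign * (x - x.mean()) / sd


def _ar1_noise(rng, n, sd, rho):
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + rng.normal(0.0, innov_sd)
    return e


def generate_community(
    spec: CommunitySimSpec, env: pd.DataFrame
) -> tuple[OligotypeTable, OligotypeTable, dict]:
    """Generate year-1 and year-2 count tables plus the taxon->module truth map.

    Returns ``(table_y1, table_y2, truth)`` where ``truth`` maps oligotype id
    to its planted module label (0 for background taxa).
    """
    rng = np.random.default_rng([spec.seed, 1])
    n_bg = int(round(spec.background_frac * spec.n_taxa))
    n_mod_taxa = spec.n_taxa - n_bg
    sizes = [n_mod_taxa // spec.n_modules] * spec.n_modules
    for k in range(n_mod_taxa - sum(sizes)):
        sizes[k] += 1
    if min(sizes) < 3:
        raise ValueError("every planted module needs at least 3 taxa")

    membership = np.concatenate(
        [np.full(s, m + 1) for m, s in enumerate(sizes)] + [np.zeros(n_bg, int)]
    ).astype(int)
    ids = [f"olig_{i:04d}" for i in range(spec.n_taxa)]
    taxonomy = pd.Series(
        [
            f"Bacteria;Phylum_{m};Class_{m};Family_{m};Genus_{i}"
            if m > 0
            else f"Bacteria;BackgroundPhylum;BackgroundClass;rare;Genus_{i}"
            for i, m in zip(range(spec.n_taxa), membership)
        ],
        index=ids,
    )

    b = np.where(
        membership > 0, rng.normal(0.0, 0.5, spec.n_taxa), rng.normal(-2.0, 0.5, spec.n_taxa)
    )
    lo, hi = spec.loading_range
    loadings = np.where(membership > 0, rng.uniform(lo, hi, spec.n_taxa), 0.0)

    drivers = {
        m: _driver_series(env, spec.module_driver_map[m])
        for m in range(1, spec.n_modules + 1)
    }

    tables = []
    truth = dict(zip(ids, (int(m) for m in membership)))
    n_per_year = spec.samples_per_year
    for yi, year in enumerate((1, 2)):
        year_mask = env["year"].to_numpy() == year
        g = np.zeros((n_per_year, spec.n_taxa))
        l_year = loadings.copy()
        if year == 2 and spec.perturb_module is not None:
            sel = membership == spec.perturb_module
            l_year[sel] = rng.uniform(-hi, hi, sel.sum())
        for m, series in drivers.items():
            sel = membership == m
            g[:, sel] = np.outer(series[year_mask], l_year[sel])
        noise = np.column_stack(
            [_ar1_noise(rng, n_per_year, spec.noise_sd, spec.ar1_rho)
             for _ in range(spec.n_taxa)]
        ) if spec.noise_sd > 0 else np.zeros((n_per_year, spec.n_taxa))
        lam = b[None, :] + g + noise
        lam -= lam.max(axis=1, keepdims=True)   # softmax stability
        p = np.exp(lam)
        p /= p.sum(axis=1, keepdims=True)
        if spec.depth_cv > 0:
            sigma = np.sqrt(np.log(1.0 + spec.depth_cv**2))
            mult = rng.lognormal(-(sigma**2) / 2.0, sigma, n_per_year)
            depths = np.maximum(100, np.round(spec.depth * mult).astype(int))
        else:
            depths = np.full(n_per_year, spec.depth)
        counts = np.vstack(
            [rng.multinomial(depths[t], p[t]) for t in range(n_per_year)]
        )
        sids = [sample_id(year, int(d)) for d in spec.sample_days]
        tables.append(
            OligotypeTable(
                counts=pd.DataFrame(counts, index=sids, columns=ids),
                dates=pd.DataFrame(
                    {"year": year, "day": spec.sample_days}, index=sids
                ),
                taxonomy=taxonomy.copy(),
            )
        )
    return tables[0], tables[1], truth


def generate_reads(
    templates: list[str],
    abundances,
    error_rate: float,
    seed: int = 0,
) -> tuple[AlignedReadSet, np.ndarray]:
    """Simulate aligned reads from equal-length templates.

    Each template k is emitted ``abundances[k]`` times; every non-gap
    position is substituted independently with probability ``error_rate``
    (uniformly to one of the three other bases).  Returns the read set and
    the true template index of every read.
    """
    abundances = np.asarray(abundances, dtype=int)
    if len(templates) == 0:
        raise ValueError("no templates")
    L = len(templates[0])
    if any(len(t) != L for t in templates):
        raise ValueError("templates must all have the same length")
    if (abundances <= 0).any() or len(abundances) != len(templates):
        raise ValueError("abundances must be positive, one per template")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    reads = []
    origins = []
    for k, (tpl, n) in enumerate(zip(templates, abundances)):
        arr = np.frombuffer(tpl.encode(), dtype=np.uint8)
        is_base = np.isin(arr, alphabet)
        for _ in range(int(n)):
            read = arr.copy()
            if error_rate > 0:
                hit = (rng.random(L) < error_rate) & is_base
                for pos in np.nonzero(hit)[0]:
                    choices = alphabet[alphabet != read[pos]]
                    read[pos] = rng.choice(choices)
            reads.append(read.tobytes().decode())
            origins.append(k)
    readset = AlignedReadSet(sequences=reads, multiplicities=np.ones(len(reads), int))
    return readset, np.asarray(origins)


def write_simulation(
    outdir,
    table_y1: OligotypeTable,
    table_y2: OligotypeTable,
    env: pd.DataFrame,
    truth: dict,
) -> None:
    """Write the generated tables, environment and truth map to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table_y1.to_tsv(outdir / "counts_y1.tsv")
    table_y2.to_tsv(outdir / "counts_y2.tsv")
    env.to_csv(outdir / "env.tsv", sep="\t")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
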
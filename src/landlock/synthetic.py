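"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates an island river system in which an amphidromous source
species (labelled ``BR``) forms one panmictic pool, and each waterfall has
landlocked one population (labelled ``YB01``, ``YB02``, ...) at a time
proportional to its height: a waterfall of height ``h`` grown at erosion rate
``E_true`` isolated its population ``t = h / E_true`` years ago.

Sequences evolve under a finite-sites TN93 substitution process with
gamma-distributed site rates.  The source pool uses a star genealogy —
independent branches of exponentially distributed depth hanging off a single
ancestor, scaled so the expected mean pairwise distance matches the configured
source diversity.  A landlocked population is founded by one pool lineage and
accrues an extra expected ``subst_rate * t`` substitutions/site on the founder
branch, so the expected source-to-population distance follows the clock line
``(source diversity + within-population term) + subst_rate * t``: the
intercept of the synthetic clock is the standing variation carried across the
waterfall, as the field study argues for the real system.

Morphology drifts toward the landlocked phenotype in proportion to genetic
divergence; site occupancy follows a logistic model with a waterfall dummy;
species richness is Poisson with a river-level random intercept.  Ground
truth (times, expected distances, coefficients) is recorded alongside every
dataset so parameter-recovery tests can close the loop.

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` sub-streams, so identical seeds give
bit-identical datasets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .seqdata import SequenceTable, decode
from .habitat import ENV_FACTORS, CONTINUOUS_FACTORS
from .morphology import CHARACTERS

# the eight dated waterfalls of the surveyed system (name -> height in m)
DATED_WATERFALLS = {
    "Nakara Fall": 27.9,
    "Mariudo Fall": 19.4,
    "Pinai Fall": 58.7,
    "Nishida Fall": 7.2,
    "Kura Fall": 7.6,
    "Geta Fall": 32.7,
    "Yuchin Right Fall": 44.2,
    "Yuchin Left Fall": 42.5,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic system.

    Defaults are the surveyed system's values: the eight dated waterfall
    heights, erosion rate 0.67 mm/yr, divergence rate 3.8%/Myr (3.8e-8 /yr),
    2086 aligned sites, source-pool mean pairwise diversity 0.00184, gamma
    shape 0.14, and 10 individuals per population.
    """

    heights_m: tuple = tuple(DATED_WATERFALLS.values())
    waterfall_names: tuple = tuple(DATED_WATERFALLS)
    erosion_rate_true: float = 0.00067  # m/yr
    subst_rate: float = 3.8e-8  # substitutions/site/yr, pairwise-divergence scale
    seq_length: int = 2086
    region_lengths: tuple = (945, 1141)  # partial ND5, full cyt-b
    source_pool_diversity: float = 0.00184  # expected mean pairwise distance
    within_pop_diversity: float = 0.0004  # free parameter; no published figure
    n_per_population: int = 10
    n_source: int = 20
    n_source_sites: int = 4  # pool individuals spread over this many BR sites
    base_frequencies: tuple = (0.28, 0.30, 0.15, 0.27)  # A, C, G, T
    kappa1: float = 15.0  # purine transition : transversion factor
    kappa2: float = 30.0  # pyrimidine transition : transversion factor
    gamma_shape: float = 0.14
    morph_slope: float = 100.0  # Euclidean score units per distance unit
    morph_baseline: float = 0.5  # shared landlocked phenotype shift (per character)
    morph_noise_sd: float = 0.1
    occupancy_coefs: dict = field(
        default_factory=lambda: {
            "intercept": -2.5, "waterfall": 5.0, "river_width_m": -1.0
        }
    )
    richness_coefs: dict = field(
        default_factory=lambda: {"intercept": 2.0, "waterfall": -1.3}
    )
    richness_random_sd: float = 0.3
    n_sites: int = 30
    n_rivers: int = 11
    seed: int = 0

    def __post_init__(self):
        if len(self.heights_m) != len(self.waterfall_names):
            raise ValueError("one name per height required")
        h = np.asarray(self.heights_m, dtype=float)
        if (h <= 0).any():
            raise ValueError("heights must be strictly positive")
        for name in ("erosion_rate_true", "seq_length", "n_per_population",
                     "gamma_shape", "n_source"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.subst_rate < 0 or self.source_pool_diversity < 0:
            raise ValueError("rates must be non-negative")
        pi = np.asarray(self.base_frequencies, dtype=float)
        if pi.shape != (4,) or abs(pi.sum() - 1.0) > 1e-12 or (pi <= 0).any():
            raise ValueError("base_frequencies must be 4 positive values summing to 1")
        if sum(self.region_lengths) != self.seq_length:
            raise ValueError("region_lengths must sum to seq_length")

    @property
    def n_waterfalls(self) -> int:
        return len(self.heights_m)

    def divergence_times(self) -> pd.Series:
        """True isolation ages in years: exactly heights / erosion rate."""
        return pd.Series(
            np.asarray(self.heights_m, dtype=float) / self.erosion_rate_true,
            index=list(self.waterfall_names),
            name="time_yr",
        )

    def expected_intercept(self) -> float:
        """Expected clock-line intercept: standing source variation carried over.

        A comparison pair is (pool member, landlocked member): the pool member
        contributes its own star-branch depth (half the pool diversity), the
        founder contributes another half, and the landlocked member a small
        within-population depth on top.
        """
        return self.source_pool_diversity + self.within_pop_diversity / 2.0

    def expected_distances(self) -> pd.Series:
        """Expected source-to-population distance per waterfall (clock line)."""
        t = self.divergence_times()
        return self.expected_intercept() + self.subst_rate * t


# ---------------------------------------------------------------------------
# TN93 finite-sites machinery


class TN93Process:
    """Reversible TN93 rate matrix, normalised to one expected sub/site/unit.

    Exposes exact finite-time transition sampling via the spectral form
    ``P(t) = D^{-1/2} U exp(L t) U' D^{1/2}`` so a branch of any length is
    simulated in one draw per site (per-site gamma rate multipliers scale the
    branch length site-wise).
    """

    def __init__(self, base_frequencies, kappa1, kappa2):
        pi = np.asarray(base_frequencies, dtype=float)
        m = np.ones((4, 4))
        m[0, 2] = m[2, 0] = kappa1  # A <-> G
        m[1, 3] = m[3, 1] = kappa2  # C <-> T
        q = m * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        q /= mu
        d_half = np.sqrt(pi)
        s = d_half[:, None] * q / d_half[None, :]
        lam, u = np.linalg.eigh((s + s.T) / 2.0)
        self.pi = pi
        self.lam = lam
        # A[k, i, j] = U[i,k]/sqrt(pi_i) * U[j,k]*sqrt(pi_j)
        self.A = np.einsum("ik,jk->kij", u / d_half[:, None], u * d_half[:, None])

    def evolve(self, codes: np.ndarray, branch: float, rates: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
        """Evolve a coded sequence along a branch of the given expected length."""
        if not np.isfinite(branch):
            raise ValueError("non-finite expected substitution count")
        if branch == 0.0:
            return codes.copy()
        t = branch * rates
        expo = np.exp(np.outer(t, self.lam))  # (L, 4)
        rows = np.einsum("sk,ksj->sj", expo, self.A[:, codes, :])
        rows = np.clip(rows, 0.0, None)
        rows /= rows.sum(axis=1, keepdims=True)
        u = rng.random(codes.size)
        return (rows.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.uint8)

    def stationary_sequence(self, length: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(4, size=length, p=self.pi).astype(np.uint8)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        name: np.random.default_rng(ss)
        for name, ss in zip(("sequences", "morphology", "habitat"), children)
    }


# ---------------------------------------------------------------------------
# sequences


def simulate_sequences(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SequenceTable:
    """Simulate the concatenated alignment for source pool + landlocked pops.

    Source individuals hang off a shared ancestor on star branches of
    exponential depth (mean = half the configured pool diversity); each
    landlocked population is founded by one such lineage plus an isolation
    branch of expected length ``subst_rate * t_i``, then its members add small
    within-population branches.  Gamma site-rate multipliers are drawn once
    and shared by every branch, matching the rate model the distance
    estimator corrects for.
    """
    rng = rng if rng is not None else _streams(config.seed)["sequences"]
    proc = TN93Process(config.base_frequencies, config.kappa1, config.kappa2)
    L = config.seq_length
    rates = rng.gamma(config.gamma_shape, 1.0 / config.gamma_shape, size=L)
    root = proc.stationary_sequence(L, rng)

    mu = config.source_pool_diversity / 2.0
    nu = config.within_pop_diversity / 2.0
    ids, pops, species, sexes, seqs = [], [], [], [], []

    def add(ind, pop, sp, codes):
        ids.append(ind)
        pops.append(pop)
        species.append(sp)
        sexes.append("male" if len(ids) % 2 else "female")
        seqs.append(decode(codes))

    for i in range(config.n_source):
        depth = rng.exponential(mu) if mu > 0 else 0.0
        codes = proc.evolve(root, depth, rates, rng)
        add(f"BR_{i + 1:03d}", f"BR{1 + i % config.n_source_sites}", "BR", codes)

    times = config.divergence_times()
    for k, (name, t) in enumerate(times.items(), start=1):
        branch = config.subst_rate * t
        if not np.isfinite(branch):
            raise ValueError(f"non-finite expected substitution count for {name}")
        if 0 < branch * L < 1:
            warnings.warn(
                f"expected substitutions for {name} below one "
                f"({branch * L:.2f}); alignment may be too short to date it"
            )
        founder_depth = rng.exponential(mu) if mu > 0 else 0.0
        ancestor = proc.evolve(root, founder_depth + branch, rates, rng)
        for i in range(config.n_per_population):
            depth = rng.exponential(nu) if nu > 0 else 0.0
            codes = proc.evolve(ancestor, depth, rates, rng)
            add(f"YB{k:02d}_{i + 1:03d}", f"YB{k:02d}", "YB", codes)

    meta = pd.DataFrame(
        {"individual_id": ids, "population": pops, "species": species, "sex": sexes}
    )
    return SequenceTable(meta=meta, sequences=seqs, region_name="ND5+cytb")


def split_regions(table: SequenceTable, region_lengths=(945, 1141)):
    """Cut a concatenated alignment back into its two region tables."""
    l1, l2 = region_lengths
    if l1 + l2 != table.alignment_length:
        raise ValueError("region lengths do not sum to the alignment length")
    first = SequenceTable(
        meta=table.meta.copy(), sequences=[s[:l1] for s in table.sequences],
        region_name="ND5",
    )
    second = SequenceTable(
        meta=table.meta.copy(), sequences=[s[l1:] for s in table.sequences],
        region_name="cytb",
    )
    return first, second


# ---------------------------------------------------------------------------
# morphology


def simulate_morphology(
    config: SimulationConfig,
    truth: pd.Series | None = None,
    meta: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Nine-character score table tracking divergence.

    Source-species individuals are centred on the all-absent profile.
    Landlocked individuals shift every character toward the all-present
    profile by ``morph_baseline + morph_slope * expected_distance / 3``:
    the baseline is the shared landlocked phenotype that makes the two
    species separable regardless of divergence time (the parallel-evolution
    signature), while the distance-proportional part encodes the finer-scale
    morphological divergence (nine characters make the profile-to-profile
    Euclidean distance three times the per-character shift, so a fit of mean
    Euclidean distance on genetic distance recovers ``morph_slope``).
    Latent scores get Gaussian noise and snap to the nearest of {0, 0.5, 1}.
    """
    rng = rng if rng is not None else _streams(config.seed)["morphology"]
    expected = truth if truth is not None else config.expected_distances()
    if meta is None:
        meta = _default_roster(config)
    shift_of_pop = {}
    for k, (_, d) in enumerate(expected.items(), start=1):
        shift_of_pop[f"YB{k:02d}"] = min(
            config.morph_baseline + config.morph_slope * float(d) / 3.0, 1.0
        )
    rows = []
    for _, r in meta.iterrows():
        shift = shift_of_pop.get(r["population"], 0.0) if r["species"] == "YB" else 0.0
        latent = shift + rng.normal(0.0, config.morph_noise_sd, size=len(CHARACTERS))
        snapped = np.clip(np.round(latent * 2.0) / 2.0, 0.0, 1.0)
        rows.append(
            {"individual_id": r["individual_id"], "population": r["population"],
             "species": r["species"], "sex": r["sex"],
             **dict(zip(CHARACTERS, snapped))}
        )
    return pd.DataFrame(rows)


def _default_roster(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    n = 0
    for i in range(config.n_source):
        n += 1
        rows.append(
            {"individual_id": f"BR_{i + 1:03d}",
             "population": f"BR{1 + i % config.n_source_sites}",
             "species": "BR", "sex": "male" if n % 2 else "female"}
        )
    for k in range(1, config.n_waterfalls + 1):
        for i in range(config.n_per_population):
            n += 1
            rows.append(
                {"individual_id": f"YB{k:02d}_{i + 1:03d}",
                 "population": f"YB{k:02d}", "species": "YB",
                 "sex": "male" if n % 2 else "female"}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# habitat


def simulate_habitat(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-site environment, focal-species presence, and richness counts.

    Sites alternate above (waterfall dummy 1) and below (0) waterfalls across
    ``n_rivers`` river systems.  Presence follows a logistic model on the
    configured coefficients; continuous coefficients act on within-dataset
    z-scores so their magnitudes are comparable.  Richness is Poisson with a
    Gaussian river-level random intercept of SD ``richness_random_sd``.
    """
    rng = rng if rng is not None else _streams(config.seed)["habitat"]
    n = config.n_sites
    rivers = [f"R{1 + i % config.n_rivers:02d}" for i in range(n)]
    env = pd.DataFrame(
        {
            "site_id": [f"S{i + 1:02d}" for i in range(n)],
            "river_id": rivers,
            "waterfall": (np.arange(n) % 2).astype(float),
            "watershed_km2": rng.lognormal(1.0, 0.8, n),
            "elevation_m": rng.uniform(5.0, 250.0, n),
            "distance_sea_km": rng.lognormal(0.8, 0.6, n),
            "river_width_m": rng.lognormal(1.8, 0.5, n),
            "water_depth_cm": rng.lognormal(3.3, 0.4, n),
            "water_velocity_cm_s": rng.lognormal(3.0, 0.5, n),
            "pebble_cm": rng.lognormal(1.5, 0.6, n),
            "slope_deg": rng.uniform(0.5, 12.0, n),
            "canopy_pct": rng.uniform(10.0, 95.0, n),
        }
    )
    z = {}
    for fac in CONTINUOUS_FACTORS:
        col = env[fac].to_numpy()
        z[fac] = (col - col.mean()) / col.std(ddof=0)

    def linpred(coefs):
        eta = np.full(n, float(coefs.get("intercept", 0.0)))
        for name, c in coefs.items():
            if name == "intercept":
                continue
            eta += c * (env["waterfall"].to_numpy() if name == "waterfall" else z[name])
        return eta

    env["presence"] = rng.binomial(1, expit(linpred(config.occupancy_coefs))).astype(int)
    river_effect = {
        r: rng.normal(0.0, config.richness_random_sd)
        for r in dict.fromkeys(rivers)
    }
    lam = np.exp(linpred(config.richness_coefs)
                 + np.array([river_effect[r] for r in rivers]))
    env["richness"] = rng.poisson(lam)
    return env


# ---------------------------------------------------------------------------
# the assembled system


@dataclass
class SyntheticSystem:
    """A complete generated dataset paired with its ground truth."""

    config: SimulationConfig
    truth: dict
    sequences: SequenceTable
    nd5: SequenceTable
    cytb: SequenceTable
    morphology: pd.DataFrame
    sites: pd.DataFrame

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.nd5.write_fasta(out / "nd5.fasta")
        self.cytb.write_fasta(out / "cytb.fasta")
        self.sequences.write_fasta(out / "concatenated.fasta")
        self.sequences.meta.to_csv(out / "metadata.csv", index=False)
        self.morphology.to_csv(out / "morphology.csv", index=False)
        self.sites.to_csv(out / "sites.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def simulate_system(config: SimulationConfig | None = None) -> SyntheticSystem:
    """Generate sequences, morphology and habitat tables plus a truth record."""
    config = config or SimulationConfig()
    streams = _streams(config.seed)
    table = simulate_sequences(config, rng=streams["sequences"])
    nd5, cytb = split_regions(table, config.region_lengths)
    expected = config.expected_distances()
    morph = simulate_morphology(
        config, truth=expected, meta=table.meta, rng=streams["morphology"]
    )
    sites = simulate_habitat(config, rng=streams["habitat"])
    times = config.divergence_times()
    truth = {
        "erosion_rate_true_m_yr": config.erosion_rate_true,
        "subst_rate_per_yr": config.subst_rate,
        "divergence_times_yr": {k: float(v) for k, v in times.items()},
        "expected_distances": {k: float(v) for k, v in expected.items()},
        "expected_intercept": config.expected_intercept(),
        "morph_slope": config.morph_slope,
        "occupancy_coefs": dict(config.occupancy_coefs),
        "richness_coefs": dict(config.richness_coefs),
        "richness_random_sd": config.richness_random_sd,
        "seed": config.seed,
    }
    return SyntheticSystem(
        config=config, truth=truth, sequences=table, nd5=nd5, cytb=cytb,
        morphology=morph, sites=sites,
    )


def config_to_json(config: SimulationConfig) -> str:
    return json.dumps(asdict(config), indent=2, sort_keys=True)


def config_from_json(text: str) -> SimulationConfig:
    raw = json.loads(text)
    for key in ("heights_m", "waterfall_names", "base_frequencies", "region_lengths"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)
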
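"""Synthetic twin-cohort generator with an ACE latent-factor structure.

The generator emulates a young-adult same-sex twin cohort: per-pair
latent factors decomposed into additive-genetic (A), common-environment
(C) and unique-environment (E) components, domain feature matrices that
are linear mixtures of those factors plus independent feature noise,
co-resident pairs with identical external-exposome rows, and binary
lifestyle items whose within-pair discordance probability is coupled to
within-pair domain distances.

Monozygotic (MZ) co-twins share the A component exactly; dizygotic (DZ)
co-twins share it with correlation 0.5 (A2 = 0.5*A1 + sqrt(0.75)*A'),
so within-pair latent correlations follow the classical-twin closed
forms a^2 + c^2 (MZ) and 0.5*a^2 + c^2 (DZ).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "DomainSpec",
    "LifestyleSpec",
    "SimulationConfig",
    "TwinCohort",
    "default_config",
    "simulate_cohort",
]

_VAR_TOL = 1e-12


@dataclass(frozen=True)
class DomainSpec:
    """Variance-component recipe for one data domain.

    Parameters
    ----------
    name : str
        Domain label (e.g. ``"proteome"``).
    n_features : int
        Number of observed features p.
    n_latent_factors : int
        Number of latent ACE factors q (q <= p).
    var_additive, var_shared, var_unique : float
        ACE variance fractions a^2, c^2, e^2; must sum to 1.
    feature_noise : float
        Fraction of each feature's variance that is independent
        measurement noise rather than latent signal, in [0, 1).
    shared_when_coresident : bool
        If True, co-resident pairs receive byte-identical rows
        (external-exposome behaviour: one geocode record per household).
    """

    name: str
    n_features: int
    n_latent_factors: int
    var_additive: float
    var_shared: float
    var_unique: float
    feature_noise: float = 0.3
    shared_when_coresident: bool = False

    def __post_init__(self) -> None:
        total = self.var_additive + self.var_shared + self.var_unique
        if abs(total - 1.0) > _VAR_TOL:
            raise ValueError(
                f"domain {self.name!r}: variance components must sum to 1, got {total!r}"
            )
        if min(self.var_additive, self.var_shared, self.var_unique) < 0:
            raise ValueError(f"domain {self.name!r}: negative variance component")
        if self.n_latent_factors > self.n_features:
            raise ValueError(
                f"domain {self.name!r}: n_latent_factors ({self.n_latent_factors}) "
                f"> n_features ({self.n_features})"
            )
        if self.n_latent_factors < 1 or self.n_features < 1:
            raise ValueError(f"domain {self.name!r}: dimensions must be positive")
        if not 0.0 <= self.feature_noise < 1.0:
            raise ValueError(f"domain {self.name!r}: feature_noise must be in [0, 1)")


@dataclass(frozen=True)
class LifestyleSpec:
    """One binary lifestyle item and its coupling to domain distances.

    ``coupling_beta`` maps domain name -> log-odds increment of the
    within-pair discordance probability per standard deviation of the
    within-pair Euclidean distance in that domain.
    """

    name: str
    baseline_discordance_prob: float
    coupling_beta: dict[str, float] = field(default_factory=dict)
    missing_prob: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_discordance_prob < 1.0:
            raise ValueError(
                f"lifestyle {self.name!r}: baseline_discordance_prob must be in (0, 1)"
            )
        if not 0.0 <= self.missing_prob < 1.0:
            raise ValueError(f"lifestyle {self.name!r}: missing_prob must be in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    n_pairs: int = 257
    prop_mz: float = 140 / 257
    domain_specs: tuple[DomainSpec, ...] = ()
    lifestyle_specs: tuple[LifestyleSpec, ...] = ()
    co_residence_prob: float = 0.32
    prop_female: float = 163 / 257
    age_mean_years: float = 22.3
    age_sd_years: float = 0.6
    age_diff_days_max: float = 160.0
    prop_same_age: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if not 0.0 <= self.prop_mz <= 1.0:
            raise ValueError("prop_mz must be in [0, 1]")
        if not 0.0 <= self.co_residence_prob <= 1.0:
            raise ValueError("co_residence_prob must be in [0, 1]")
        names = [d.name for d in self.domain_specs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate domain names")


@dataclass
class TwinCohort:
    """A simulated cohort: pair metadata, domain matrices, lifestyle, truth.

    ``pairs`` has one row per twin pair; ``domains`` maps domain name to
    an individuals x features DataFrame indexed by twin id; ``lifestyle``
    holds per-twin binary items (NaN = missing). ``truth`` records the
    planted parameters (config echo, co-residence, latent factors,
    per-pair distances, planted discordance) for recovery tests.
    """

    pairs: pd.DataFrame
    domains: dict[str, pd.DataFrame]
    lifestyle: pd.DataFrame
    truth: dict

    def to_dir(self, path: str | Path) -> None:
        """Write the cohort as delimited text plus a JSON truth sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(path / "pairs.csv", index=False)
        self.lifestyle.to_csv(path / "lifestyle.csv", index_label="twin_id")
        for name, mat in self.domains.items():
            mat.to_csv(path / f"{name}.csv", index_label="twin_id")
        sidecar = {
            "config": self.truth["config"],
            "co_resident": self.truth["co_resident"],
            "discordance": self.truth["discordance"],
        }
        with open(path / "truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_dir(cls, path: str | Path) -> "TwinCohort":
        from .io import read_domain_csv, read_lifestyle, read_pairs

        path = Path(path)
        pairs = read_pairs(path / "pairs.csv")
        lifestyle = read_lifestyle(path / "lifestyle.csv")
        reserved = {"pairs.csv", "lifestyle.csv"}
        domains = {
            p.stem: read_domain_csv(p)
            for p in sorted(path.glob("*.csv"))
            if p.name not in reserved
        }
        truth: dict = {}
        truth_path = path / "truth.json"
        if truth_path.exists():
            truth = json.loads(truth_path.read_text())
        return cls(pairs=pairs, domains=domains, lifestyle=lifestyle, truth=truth)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Cohort defaults: 257 same-sex pairs (140 MZ / 117 DZ), four domains.

    Domain dimensions mirror a young-adult multi-omics twin cohort
    (proteome 439, metabolome 140, epigenetic age acceleration 8,
    external exposome 65 features). Omics domains carry a moderate
    additive-genetic component (a2=0.5, c2=0.2, e2=0.3); the external
    exposome is purely environmental (a2=0) with a large shared
    component and a point mass of identical rows for co-resident pairs,
    yielding the wide, left-skewed similarity distribution such data
    show. Lifestyle items cover leisure, social behaviour, substance
    use and education; substance-use items are coupled to exposome
    (and weakly to omics) within-pair distances.
    """
    domains = (
        DomainSpec("proteome", 439, 10, 0.5, 0.2, 0.3, feature_noise=0.2),
        DomainSpec("metabolome", 140, 8, 0.5, 0.2, 0.3, feature_noise=0.2),
        DomainSpec("eaa", 8, 3, 0.5, 0.2, 0.3, feature_noise=0.2),
        DomainSpec(
            "exposome", 65, 3, 0.0, 0.6, 0.4,
            feature_noise=0.05, shared_when_coresident=True,
        ),
    )
    lifestyle = (
        LifestyleSpec("video_games", 0.25),
        LifestyleSpec("watching_videos", 0.30),
        LifestyleSpec("playing_instrument", 0.20),
        LifestyleSpec("reading", 0.30),
        LifestyleSpec("going_out", 0.30, {"exposome": 0.4}),
        LifestyleSpec("dancing", 0.25),
        LifestyleSpec("club_participation", 0.20),
        LifestyleSpec("fast_food", 0.30),
        LifestyleSpec("going_to_bars", 0.30, {"exposome": 0.2}),
        LifestyleSpec("smoking", 0.25, {"exposome": 0.3, "eaa": 0.3}),
        LifestyleSpec("alcohol_consumption", 0.30, {"exposome": 0.2}),
        LifestyleSpec("drinking_to_intoxication", 0.30, {"exposome": 0.6, "proteome": 0.2}),
        LifestyleSpec("vocational_degree", 0.25, {"exposome": 0.3}),
        LifestyleSpec("early_sexual_initiation", 0.25),
    )
    base = dict(
        n_pairs=257,
        prop_mz=140 / 257,
        domain_specs=domains,
        lifestyle_specs=lifestyle,
        co_residence_prob=0.32,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def _simulate_latent(
    spec: DomainSpec, is_mz: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Latent ACE factors for both co-twins: (n_pairs, q) each."""
    n = is_mz.shape[0]
    q = spec.n_latent_factors
    a = np.sqrt(spec.var_additive)
    c = np.sqrt(spec.var_shared)
    e = np.sqrt(spec.var_unique)
    a1 = rng.standard_normal((n, q))
    # DZ: corr(A1, A2) = 0.5 exactly via A2 = 0.5 A1 + sqrt(0.75) A'
    a2 = np.where(is_mz[:, None], a1, 0.5 * a1 + np.sqrt(0.75) * rng.standard_normal((n, q)))
    shared = rng.standard_normal((n, q))
    f1 = a * a1 + c * shared + e * rng.standard_normal((n, q))
    f2 = a * a2 + c * shared + e * rng.standard_normal((n, q))
    return f1, f2


def _mix_features(
    spec: DomainSpec, f1: np.ndarray, f2: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed features: unit-variance mixtures of latent factors plus noise."""
    q, p = spec.n_latent_factors, spec.n_features
    loadings = rng.standard_normal((q, p))
    loadings /= np.linalg.norm(loadings, axis=0, keepdims=True)
    sig = np.sqrt(1.0 - spec.feature_noise)
    noise = np.sqrt(spec.feature_noise)
    x1 = sig * (f1 @ loadings) + noise * rng.standard_normal((f1.shape[0], p))
    x2 = sig * (f2 @ loadings) + noise * rng.standard_normal((f2.shape[0], p))
    return x1, x2


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> TwinCohort:
    """Generate a twin cohort under ``config``; deterministic given the seed.

    Discordance for lifestyle item v is Bernoulli with
    ``logit(p) = logit(baseline) + sum_d beta_{v,d} * z_d`` where z_d is
    the pair's standardized within-pair Euclidean distance in domain d.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_pairs

    n_mz = int(round(config.prop_mz * n))
    zyg = np.array(["MZ"] * n_mz + ["DZ"] * (n - n_mz))
    rng.shuffle(zyg)
    is_mz = zyg == "MZ"

    width = len(str(n))
    pair_ids = [f"P{i + 1:0{width}d}" for i in range(n)]
    twin1 = [f"{p}_1" for p in pair_ids]
    twin2 = [f"{p}_2" for p in pair_ids]
    twin_ids = [t for pair in zip(twin1, twin2) for t in pair]

    sex = np.where(rng.random(n) < config.prop_female, "F", "M")
    co_res = rng.random(n) < config.co_residence_prob

    age1 = rng.normal(config.age_mean_years, config.age_sd_years, n)
    same_age = rng.random(n) < config.prop_same_age
    diff_days = rng.uniform(1.0, config.age_diff_days_max, n) * rng.choice([-1, 1], n)
    age2 = np.where(same_age, age1, age1 + diff_days / 365.25)
    # Separation age: co-resident pairs have not yet separated at sampling,
    # so their recorded age is censored at (just beyond) the blood-draw age.
    sep = np.clip(rng.normal(19.0, 2.0, n), 14.0, None)
    age_left_home = np.where(co_res, np.maximum(age1, age2) + np.abs(rng.normal(0.5, 0.5, n)), sep)
    age_left_home = np.where(~co_res & (rng.random(n) < 0.05), np.nan, age_left_home)

    domains: dict[str, pd.DataFrame] = {}
    latent: dict[str, np.ndarray] = {}
    dist_z = pd.DataFrame(index=pd.Index(pair_ids, name="pair_id"))
    for spec in config.domain_specs:
        f1, f2 = _simulate_latent(spec, is_mz, rng)
        x1, x2 = _mix_features(spec, f1, f2, rng)
        if spec.shared_when_coresident:
            x2[co_res] = x1[co_res]
            f2[co_res] = f1[co_res]
        rows = np.empty((2 * n, spec.n_features))
        rows[0::2] = x1
        rows[1::2] = x2
        cols = [f"{spec.name}_f{j + 1}" for j in range(spec.n_features)]
        domains[spec.name] = pd.DataFrame(
            rows, index=pd.Index(twin_ids, name="twin_id"), columns=cols
        )
        latent[spec.name] = np.stack([f1, f2], axis=1)
        dist = np.linalg.norm(x1 - x2, axis=1)
        sd = dist.std(ddof=1)
        dist_z[spec.name] = (dist - dist.mean()) / sd if sd > 0 else 0.0

    lifestyle = pd.DataFrame(index=pd.Index(twin_ids, name="twin_id"))
    disc_truth = pd.DataFrame(index=pd.Index(pair_ids, name="pair_id"))
    disc_prob = pd.DataFrame(index=pd.Index(pair_ids, name="pair_id"))
    for spec in config.lifestyle_specs:
        eta = logit(spec.baseline_discordance_prob) * np.ones(n)
        for dom, beta in spec.coupling_beta.items():
            if dom not in dist_z.columns:
                raise ValueError(f"lifestyle {spec.name!r} couples to unknown domain {dom!r}")
            eta = eta + beta * dist_z[dom].to_numpy()
        prob = expit(eta)
        disc = rng.random(n) < prob
        v1 = (rng.random(n) < 0.5).astype(float)
        v2 = np.where(disc, 1.0 - v1, v1)
        miss = rng.random(n) < spec.missing_prob
        which = rng.random(n) < 0.5
        v1 = np.where(miss & which, np.nan, v1)
        v2 = np.where(miss & ~which, np.nan, v2)
        col = np.empty(2 * n)
        col[0::2] = v1
        col[1::2] = v2
        lifestyle[spec.name] = col
        disc_truth[spec.name] = disc.astype(int)
        disc_prob[spec.name] = prob

    pairs = pd.DataFrame(
        {
            "pair_id": pair_ids,
            "twin1_id": twin1,
            "twin2_id": twin2,
            "zygosity": zyg,
            "sex": sex,
            "age_blood_twin1": age1,
            "age_blood_twin2": age2,
            "age_left_home": age_left_home,
            "co_resident": co_res,
        }
    )

    truth = {
        "config": _config_to_jsonable(config, seed),
        "co_resident": co_res.astype(int).tolist(),
        "discordance": {v: disc_truth[v].tolist() for v in disc_truth.columns},
        "discordance_prob": disc_prob,
        "domain_distance_z": dist_z,
        "latent": latent,
    }
    return TwinCohort(pairs=pairs, domains=domains, lifestyle=lifestyle, truth=truth)


def _config_to_jsonable(config: SimulationConfig, seed: int) -> dict:
    out = dataclasses.asdict(config)
    out["seed"] = seed
    out["domain_specs"] = [dataclasses.asdict(d) for d in config.domain_specs]
    out["lifestyle_specs"] = [dataclasses.asdict(l) for l in config.lifestyle_specs]
    return out
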
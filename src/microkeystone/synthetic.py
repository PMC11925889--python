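"""Coupled microbiome / transcriptome / trait simulator with planted truth.

The community generator draws per-feature latent log-abundances from a
Gaussian copula whose correlation backbone plants a hub–satellite block,
exponentiates them to a composition, and samples multinomial counts at a
log-uniform sequencing depth.  Group structure is planted as fold-enrichments
of designated indicator features (and of the hub block in its home group).
Gene counts are negative-binomial around log-linear means, optionally coupled
to taxon latents; traits are linear in standardised latents plus noise.

Every planted element is recorded in a :class:`SyntheticTruth` so recovery
tests can score sensitivity against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountTable, SampleMetadata, TraitTable, ValidationError

__all__ = [
    "CommunityConfig",
    "ExpressionConfig",
    "TraitConfig",
    "SyntheticTruth",
    "generate_community",
    "generate_expression",
    "generate_traits",
]

# Per-tier (target mean share of the composition, lognormal sigma).  Shares
# are chosen so the default 300-feature community sums to ~1 before the
# softmax renormalisation; sigmas realise the within/across-threshold
# behaviour each class name implies.
TIER_PARAMS: dict[str, tuple[float, float]] = {
    "RT": (8e-5, 0.30),
    "CRT": (4.5e-4, 0.90),
    "MT": (3e-3, 0.25),
    "CAT": (4e-3, 0.80),
    "CRAT": (1.5e-3, 1.60),
    "AT": (3e-2, 0.25),
}

DEFAULT_TIER_PROPORTIONS: dict[str, float] = {
    "RT": 0.40,
    "CRT": 0.16,
    "MT": 0.20,
    "CAT": 0.09,
    "CRAT": 0.08,
    "AT": 0.07,
}


@dataclass
class CommunityConfig:
    groups: tuple[str, ...] = ("Control", "HA", "P", "HAP")
    n_per_group: int = 15
    n_features: int = 300
    tier_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TIER_PROPORTIONS)
    )
    depth_range: tuple[int, int] = (20_000, 60_000)
    n_satellites: int = 10
    rho_hub: float = 0.8
    hub_group: str | None = None  # optional group in which the hub block is enriched
    indicators_per_group: int = 2
    # Fold-enrichment of planted group specialists.  With g groups the
    # specificity of an f-fold specialist is f/(f+g-1) in expectation, so the
    # >0.7 key rule needs f>7 at g=4; 20 leaves margin for the lognormal
    # group-mean noise of high-variance tiers.
    indicator_fold: float = 20.0
    allow_hub_indicator_overlap: bool = False


@dataclass
class ExpressionConfig:
    n_genes: int = 400
    base_log_mean: float = float(np.log(100.0))
    base_log_sd: float = 1.0
    dispersion: float = 0.1
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    n_de: int = 20
    de_pair: tuple[str, str] = ("Control", "HA")
    de_log2fc: float = 2.0
    n_coupled: int = 5
    coupling_coefficient: float = 1.0
    coupling_noise_sd: float = 0.1
    coupling_taxon: str | None = None  # defaults to the hub


@dataclass
class TraitConfig:
    # trait -> ({entity: weight}, noise_sd); entities are "taxon:<id>" /
    # "gene:<id>"; "hub" and "coupled0" resolve against the truth record.
    models: dict[str, tuple[dict[str, float], float]] = field(
        default_factory=lambda: {
            "exploration_ratio": ({"hub": 1.0}, 0.3),
            "open_arm_duration": ({}, 1.0),
            "escape_latency": ({}, 1.0),
            "taoc": ({}, 1.0),
            "sod": ({"coupled0": 1.0}, 0.3),
            "cat_activity": ({}, 1.0),
            "mda": ({"hub": -1.0}, 0.3),
        }
    )


@dataclass
class SyntheticTruth:
    seed: int
    group_design: dict[str, int]
    tier_map: dict[str, str]
    indicator_map: dict[str, dict]  # feature -> {"groups": [...], "fold": f}
    hub_id: str
    satellites: list[str]
    rho_hub: float
    de_genes: dict[str, dict] = field(default_factory=dict)
    coupling_map: dict[str, dict] = field(default_factory=dict)
    trait_model: dict[str, dict] = field(default_factory=dict)
    # latent matrices for downstream coupling (not serialised)
    taxon_latent: pd.DataFrame | None = field(default=None, repr=False)
    taxon_log_abund: pd.DataFrame | None = field(default=None, repr=False)
    gene_latent: pd.DataFrame | None = field(default=None, repr=False)
    sample_groups: pd.Series | None = field(default=None, repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "group_design": self.group_design,
            "tier_map": self.tier_map,
            "indicator_map": self.indicator_map,
            "hub_id": self.hub_id,
            "satellites": self.satellites,
            "rho_hub": self.rho_hub,
            "de_genes": self.de_genes,
            "coupling_map": self.coupling_map,
            "trait_model": self.trait_model,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _tier_counts(proportions: dict[str, float], n_features: int) -> dict[str, int]:
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValidationError(
            f"tier proportions must sum to 1, got {sum(proportions.values()):.6g}"
        )
    raw = {t: proportions[t] * n_features for t in TIER_PARAMS if t in proportions}
    counts = {t: int(np.floor(v)) for t, v in raw.items()}
    short = n_features - sum(counts.values())
    for t in sorted(raw, key=lambda t: raw[t] - counts[t], reverse=True)[:short]:
        counts[t] += 1
    return counts


def generate_community(
    config: CommunityConfig | None = None, seed: int = 0
) -> tuple[CountTable, SampleMetadata, SyntheticTruth]:
    """Simulate a 4-group ASV count table with planted structure."""
    config = config or CommunityConfig()
    rng = np.random.default_rng(seed)

    sample_ids, labels = [], []
    for g in config.groups:
        for i in range(config.n_per_group):
            sample_ids.append(f"{g}_{i + 1:02d}")
            labels.append(g)
    n_samples = len(sample_ids)

    counts_per_tier = _tier_counts(config.tier_proportions, config.n_features)
    feature_ids, tiers = [], []
    k = 0
    for tier in TIER_PARAMS:
        for _ in range(counts_per_tier.get(tier, 0)):
            k += 1
            feature_ids.append(f"ASV{k:04d}")
            tiers.append(tier)
    tier_map = dict(zip(feature_ids, tiers))
    n_features = len(feature_ids)

    share = np.array([TIER_PARAMS[t][0] for t in tiers])
    sigma = np.array([TIER_PARAMS[t][1] for t in tiers])
    # lognormal mean correction keeps the realised mean share near its target
    mu = np.log(share) - sigma ** 2 / 2.0

    # hub block: first CAT feature plus the following satellites
    cat_idx = [i for i, t in enumerate(tiers) if t == "CAT"]
    if len(cat_idx) < config.n_satellites + 1:
        raise ValidationError("not enough CAT-tier features for the hub block")
    hub_idx = cat_idx[0]
    sat_idx = cat_idx[1 : config.n_satellites + 1]
    hub_id = feature_ids[hub_idx]
    satellites = [feature_ids[i] for i in sat_idx]

    # indicator features per group, drawn from CAT/MT tiers outside the block
    block = {hub_idx, *sat_idx}
    eligible = [
        i for i, t in enumerate(tiers) if t in ("CAT", "MT") and i not in block
    ]
    need = config.indicators_per_group * len(config.groups)
    if len(eligible) < need:
        raise ValidationError("not enough eligible features for indicators")
    indicator_map: dict[str, dict] = {}
    chosen = list(rng.choice(eligible, size=need, replace=False))
    group_of_indicator: dict[int, str] = {}
    for j, g in enumerate(config.groups):
        for i in chosen[
            j * config.indicators_per_group : (j + 1) * config.indicators_per_group
        ]:
            indicator_map[feature_ids[i]] = {"groups": [g], "fold": config.indicator_fold}
            group_of_indicator[i] = g
    if not config.allow_hub_indicator_overlap and block & set(group_of_indicator):
        raise ValidationError("hub block overlaps indicator set")

    # Gaussian copula latents with the hub-satellite backbone
    z = rng.standard_normal((n_features, n_samples))
    z[sat_idx] = config.rho_hub * z[hub_idx] + np.sqrt(
        1.0 - config.rho_hub ** 2
    ) * z[sat_idx]

    labels_arr = np.array(labels)
    log_abund = mu[:, None] + sigma[:, None] * z
    for i, g in group_of_indicator.items():
        log_abund[i, labels_arr == g] += np.log(config.indicator_fold)
    if config.hub_group is not None:
        if config.hub_group not in config.groups:
            raise ValidationError(f"unknown hub_group {config.hub_group!r}")
        in_home = labels_arr == config.hub_group
        for i in [hub_idx, *sat_idx]:
            log_abund[i, in_home] += np.log(config.indicator_fold)
        indicator_map[hub_id] = {
            "groups": [config.hub_group],
            "fold": config.indicator_fold,
        }
        for s in satellites:
            indicator_map[s] = {
                "groups": [config.hub_group],
                "fold": config.indicator_fold,
            }

    composition = np.exp(log_abund)
    composition /= composition.sum(axis=0)

    lo, hi = config.depth_range
    depths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples)).astype(int)
    counts = np.column_stack(
        [rng.multinomial(depths[j], composition[:, j]) for j in range(n_samples)]
    )

    table = CountTable(pd.DataFrame(counts, index=feature_ids, columns=sample_ids))
    meta = SampleMetadata(pd.Series(labels, index=sample_ids, name="group"))
    truth = SyntheticTruth(
        seed=seed,
        group_design={g: config.n_per_group for g in config.groups},
        tier_map=tier_map,
        indicator_map=indicator_map,
        hub_id=hub_id,
        satellites=satellites,
        rho_hub=config.rho_hub,
        taxon_latent=pd.DataFrame(z, index=feature_ids, columns=sample_ids),
        taxon_log_abund=pd.DataFrame(
            log_abund, index=feature_ids, columns=sample_ids
        ),
        sample_groups=meta.groups,
    )
    return table, meta, truth


def generate_expression(
    truth: SyntheticTruth, config: ExpressionConfig | None = None, seed: int = 0
) -> CountTable:
    """Simulate a gene count table partially coupled to the community."""
    config = config or ExpressionConfig()
    rng = np.random.default_rng(seed)
    if truth.taxon_latent is None:
        raise ValidationError("truth record lacks taxon latents")
    sample_ids = list(truth.taxon_latent.columns)
    n_samples = len(sample_ids)

    gene_ids = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    base = rng.normal(config.base_log_mean, config.base_log_sd, size=config.n_genes)
    sf = np.exp(
        rng.uniform(
            np.log(config.size_factor_range[0]),
            np.log(config.size_factor_range[1]),
            size=n_samples,
        )
    )
    log_mu = base[:, None] + np.log(sf)[None, :]

    de_genes: dict[str, dict] = {}
    if config.n_de > 0:
        group_a, group_b = config.de_pair
        groups = truth.sample_groups.to_numpy()
        if group_b not in groups or group_a not in groups:
            raise ValidationError(f"de_pair {config.de_pair} not in the design")
        in_b = groups == group_b
        de_idx = rng.choice(config.n_genes, size=config.n_de, replace=False)
        for j, gi in enumerate(de_idx):
            sign = 1.0 if j % 2 == 0 else -1.0
            lfc = sign * config.de_log2fc
            log_mu[gi, in_b] += lfc * np.log(2.0)
            de_genes[gene_ids[gi]] = {"pair": list(config.de_pair), "log2fc": lfc}

    coupling_map: dict[str, dict] = {}
    if config.n_coupled > 0:
        taxon = config.coupling_taxon or truth.hub_id
        if taxon not in truth.taxon_log_abund.index:
            raise ValidationError(f"coupling to unknown taxon {taxon!r}")
        # couple to the realised log-abundance (group shifts included), the
        # quantity a host readout would actually respond to
        zt = truth.taxon_log_abund.loc[taxon].to_numpy()
        zt = (zt - zt.mean()) / zt.std()
        free = [i for i in range(config.n_genes) if gene_ids[i] not in de_genes]
        coupled_idx = rng.choice(free, size=config.n_coupled, replace=False)
        for gi in coupled_idx:
            noise = rng.normal(0.0, config.coupling_noise_sd, size=n_samples)
            log_mu[gi] += config.coupling_coefficient * zt + noise
            coupling_map[gene_ids[gi]] = {
                "taxon": taxon,
                "coefficient": config.coupling_coefficient,
                "noise_sd": config.coupling_noise_sd,
            }

    mu = np.exp(log_mu)
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    truth.de_genes = de_genes
    truth.coupling_map = coupling_map
    truth.gene_latent = pd.DataFrame(log_mu, index=gene_ids, columns=sample_ids)
    return CountTable(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))


def _resolve_entity(name: str, truth: SyntheticTruth) -> np.ndarray:
    if name == "hub":
        name = f"taxon:{truth.hub_id}"
    elif name == "coupled0":
        if not truth.coupling_map:
            raise ValidationError("no coupled genes in truth record")
        name = f"gene:{sorted(truth.coupling_map)[0]}"
    kind, _, ident = name.partition(":")
    if kind == "taxon":
        if truth.taxon_log_abund is None or ident not in truth.taxon_log_abund.index:
            raise ValidationError(f"unknown taxon {ident!r} in trait model")
        v = truth.taxon_log_abund.loc[ident].to_numpy()
    elif kind == "gene":
        if truth.gene_latent is None or ident not in truth.gene_latent.index:
            raise ValidationError(f"unknown gene {ident!r} in trait model")
        v = truth.gene_latent.loc[ident].to_numpy()
    else:
        raise ValidationError(f"unknown trait-model entity {name!r}")
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def generate_traits(
    truth: SyntheticTruth, config: TraitConfig | None = None, seed: int = 0
) -> TraitTable:
    """Simulate behaviour/antioxidant traits as linear readouts of latents."""
    config = config or TraitConfig()
    rng = np.random.default_rng(seed)
    if truth.taxon_latent is None:
        raise ValidationError("truth record lacks taxon latents")
    sample_ids = list(truth.taxon_latent.columns)
    n = len(sample_ids)

    data = {}
    trait_model: dict[str, dict] = {}
    for trait, (weights, noise_sd) in config.models.items():
        if not weights and noise_sd == 0:
            raise ValidationError(
                f"trait {trait!r} has no weights and zero noise: zero-variance"
            )
        value = np.zeros(n)
        for entity, w in weights.items():
            value += w * _resolve_entity(entity, truth)
        value += rng.normal(0.0, noise_sd, size=n)
        data[trait] = value
        trait_model[trait] = {"weights": dict(weights), "noise_sd": noise_sd}
    truth.trait_model = trait_model
    return TraitTable(pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id")))
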
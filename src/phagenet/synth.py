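"""Synthetic two-domain (bacteria + phage) abundance tables with known ground truth.

The generator emulates the structure of TPM-scale metagenomic abundance tables:

* two domains, with bacterial richness exceeding phage richness;
* log-normal-like abundances closed to a fixed per-sample total;
* group structure (a "diet"/"family" analogue) as a log-scale mean shift of
  tunable effect size;
* planted correlated taxon blocks (within- or cross-domain, either sign),
  realized through shared latent Gaussian factors;
* planted hub ("keystone") taxa tied to a set of satellite taxa.

The latent model is multivariate Gaussian on log abundances. A block with
target correlation ρ gives its members loading √|ρ| on one shared factor
(alternating loading signs when ρ < 0, so cross-sign pairs correlate at ρ and
same-sign pairs at |ρ|). A hub loads 1.0 on its own factor while satellites
load ±√c (``hub_satellite_c``, default 0.5), giving hub–satellite latent
correlation ±√c ≈ 0.71 and satellite–satellite correlation c — the weakest
mutual satellite coupling a positive-definite correlation matrix allows at
that hub coupling. Abundances are ``exp(latent)`` closed to ``tpm_total``;
closure distorts Pearson correlations but leaves rank (Spearman) structure
largely intact, which is what the downstream network screen measures.

Everything is driven by one seeded :class:`numpy.random.Generator`, so a
given config is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import AbundanceTable, write_tables

_DIETS = ("carnivore", "herbivore", "omnivore", "bamboo-eating")


@dataclass
class BlockSpec:
    """A planted correlated block: member taxon ids and a target latent correlation."""

    members: tuple[str, ...]
    rho: float

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"block correlation {self.rho} outside [-1, 1]")
        if len(self.members) < 2:
            raise ValueError("a block needs at least 2 members")


@dataclass
class HubSpec:
    """A planted hub taxon with its satellites; sign flips the hub–satellite coupling."""

    hub: str
    satellites: tuple[str, ...]
    sign: int = 1

    def __post_init__(self) -> None:
        self.satellites = tuple(self.satellites)
        if self.sign not in (-1, 1):
            raise ValueError("hub sign must be +1 or -1")
        if self.hub in self.satellites:
            raise ValueError("hub cannot be its own satellite")


@dataclass
class SynthConfig:
    n_groups: int = 3
    samples_per_group: int = 20
    n_bacteria: int = 40
    n_phages: int = 20
    group_effect_size: float = 0.0
    block_specs: Sequence[BlockSpec] = field(default_factory=tuple)
    hub_specs: Sequence[HubSpec] = field(default_factory=tuple)
    noise_sd: float = 1.0
    tpm_total: float = 1_000_000.0
    zero_fraction: float = 0.0
    hub_satellite_c: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.samples_per_group < 1:
            raise ValueError("n_groups and samples_per_group must be positive")
        if self.n_bacteria < 1 or self.n_phages < 1:
            raise ValueError("taxon counts must be positive")
        if self.n_bacteria <= self.n_phages:
            raise ValueError("n_bacteria must exceed n_phages (observed richness ordering)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.tpm_total <= 0:
            raise ValueError("tpm_total must be positive")
        if not 0.0 <= self.zero_fraction < 1.0:
            raise ValueError("zero_fraction must be in [0, 1)")
        if not 0.0 < self.hub_satellite_c < 1.0:
            raise ValueError("hub_satellite_c must be in (0, 1)")
        if self.group_effect_size < 0:
            raise ValueError("group_effect_size must be non-negative")
        self.block_specs = tuple(self.block_specs)
        self.hub_specs = tuple(self.hub_specs)
        ids = set(self.taxon_ids())
        planted: set[str] = set()
        for b in self.block_specs:
            members = set(b.members)
            unknown = members - ids
            if unknown:
                raise ValueError(f"block members not in taxon set: {sorted(unknown)}")
            if members & planted:
                raise ValueError("planted blocks/hubs must be disjoint")
            planted |= members
        for h in self.hub_specs:
            members = {h.hub, *h.satellites}
            unknown = members - ids
            if unknown:
                raise ValueError(f"hub members not in taxon set: {sorted(unknown)}")
            if len(h.satellites) > self.n_bacteria + self.n_phages - 1:
                raise ValueError("satellite count exceeds available taxa")
            if members & planted:
                raise ValueError("planted blocks/hubs must be disjoint")
            planted |= members

    def taxon_ids(self) -> list[str]:
        bact = [f"B{i:04d}" for i in range(1, self.n_bacteria + 1)]
        phage = [f"P{i:04d}" for i in range(1, self.n_phages + 1)]
        return bact + phage

    def sample_ids(self) -> list[str]:
        return [
            f"G{g + 1}S{s + 1:03d}"
            for g in range(self.n_groups)
            for s in range(self.samples_per_group)
        ]


@dataclass
class GroundTruth:
    """What was planted: blocks, hubs, group assignment, latent group means."""

    planted_blocks: tuple[BlockSpec, ...]
    planted_hubs: tuple[HubSpec, ...]
    group_assignments: dict[str, str]
    latent_means: pd.DataFrame  # taxa × groups, log-scale

    def to_json(self, path) -> None:
        payload = {
            "planted_blocks": [
                {"members": list(b.members), "rho": b.rho} for b in self.planted_blocks
            ],
            "planted_hubs": [
                {"hub": h.hub, "satellites": list(h.satellites), "sign": h.sign}
                for h in self.planted_hubs
            ],
            "group_assignments": self.group_assignments,
            "latent_means": self.latent_means.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _latent_loadings(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Factor loadings L (taxa × factors) and idiosyncratic sds, unit total variance."""
    taxa = config.taxon_ids()
    pos = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    n_factors = len(config.block_specs) + len(config.hub_specs)
    L = np.zeros((n, n_factors))
    f = 0
    for b in config.block_specs:
        load = np.sqrt(abs(b.rho))
        for j, t in enumerate(b.members):
            sign = -1.0 if (b.rho < 0 and j % 2 == 1) else 1.0
            L[pos[t], f] = sign * load
        f += 1
    c = config.hub_satellite_c
    for h in config.hub_specs:
        L[pos[h.hub], f] = 1.0
        for t in h.satellites:
            L[pos[t], f] = h.sign * np.sqrt(c)
        f += 1
    resid_var = 1.0 - (L**2).sum(axis=1)
    if (resid_var < -1e-9).any():
        raise ValueError("factor loadings exceed unit variance")
    return L, np.sqrt(np.clip(resid_var, 0.0, None))


def generate_community(config: SynthConfig) -> tuple[AbundanceTable, GroundTruth]:
    """Draw one abundance table plus its ground truth from the latent model."""
    rng = np.random.default_rng(config.seed)
    taxa = config.taxon_ids()
    samples = config.sample_ids()
    n_taxa, n_samples = len(taxa), len(samples)
    groups = [f"G{g + 1}" for g in range(config.n_groups)]

    # log-scale group means: a fixed random direction per group, scaled by effect size
    mu = config.group_effect_size * rng.standard_normal((n_taxa, config.n_groups))
    latent_means = pd.DataFrame(mu, index=taxa, columns=groups)

    L, resid_sd = _latent_loadings(config)
    n_factors = L.shape[1]
    factors = rng.standard_normal((n_factors, n_samples))
    eps = rng.standard_normal((n_taxa, n_samples))
    z = L @ factors + resid_sd[:, None] * eps  # unit-variance correlated normals

    group_of_sample = np.repeat(np.arange(config.n_groups), config.samples_per_group)
    log_abund = mu[:, group_of_sample] + config.noise_sd * z
    abund = np.exp(log_abund)

    if config.zero_fraction > 0:
        mask = rng.random((n_taxa, n_samples)) < config.zero_fraction
        # never zero out a whole sample column
        full_cols = mask.all(axis=0)
        mask[rng.integers(0, n_taxa, size=full_cols.sum()), np.where(full_cols)[0]] = False
        abund = np.where(mask, 0.0, abund)

    abund = abund / abund.sum(axis=0, keepdims=True) * config.tpm_total

    values = pd.DataFrame(abund, index=taxa, columns=samples)
    taxonomy = pd.DataFrame(
        {
            "domain": ["bacteria"] * config.n_bacteria + ["phage"] * config.n_phages,
            "phylum": [f"SynPhylum{(i % 5) + 1}" for i in range(n_taxa)],
            "order": [f"SynOrder{(i % 8) + 1}" for i in range(n_taxa)],
            "family": [f"SynFamily{(i % 12) + 1}" for i in range(n_taxa)],
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    metadata = pd.DataFrame(
        {
            "group": [groups[g] for g in group_of_sample],
            "diet": [_DIETS[g % len(_DIETS)] for g in group_of_sample],
            "host_order": [f"HostOrder{(g % 3) + 1}" for g in group_of_sample],
            "host_family": [f"HostFamily{g + 1}" for g in group_of_sample],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    table = AbundanceTable(values, taxonomy, metadata)
    truth = GroundTruth(
        planted_blocks=tuple(config.block_specs),
        planted_hubs=tuple(config.hub_specs),
        group_assignments=dict(zip(samples, metadata["group"])),
        latent_means=latent_means,
    )
    return table, truth


def plant_keystone_scenario(config: SynthConfig) -> tuple[AbundanceTable, GroundTruth]:
    """Generate a community whose ground truth contains at least one strong hub.

    Requires a hub spec with ≥ 12 satellites so the hub can dominate degree
    and closeness in the screened network.
    """
    if not any(len(h.satellites) >= 12 for h in config.hub_specs):
        raise ValueError("plant_keystone_scenario needs a hub_spec with >= 12 satellites")
    return generate_community(config)


def default_hub_config(
    n_satellites: int = 15,
    n_bacteria: int = 40,
    n_phages: int = 20,
    samples_per_group: int = 40,
    sign: int = 1,
    seed: int = 0,
) -> SynthConfig:
    """One-group, one-hub scenario used by the keystone-recovery checks."""
    hub = HubSpec(
        hub="B0001",
        satellites=tuple(f"B{i:04d}" for i in range(2, n_satellites + 2)),
        sign=sign,
    )
    return SynthConfig(
        n_groups=1,
        samples_per_group=samples_per_group,
        n_bacteria=n_bacteria,
        n_phages=n_phages,
        hub_specs=(hub,),
        seed=seed,
    )


def write_synthetic_bundle(config: SynthConfig, out_dir) -> dict[str, str]:
    """Emit the TSV trio plus a ground-truth JSON for a config."""
    table, truth = generate_community(config)
    paths = write_tables(table, out_dir, prefix="synthetic")
    import os

    truth_path = os.path.join(out_dir, "synthetic_ground_truth.json")
    truth.to_json(truth_path)
    paths["ground_truth"] = truth_path
    return paths
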
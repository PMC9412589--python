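"""Synthetic multi-fraction proteomics datasets with recoverable ground truth.

The generator emulates the structure of a two-group (control vs MB), four-
fraction (total, CPLL, Mv, Ex) label-free CSF proteomics experiment:

* per-protein baseline abundance drawn log-uniform over a wide (10 log2-unit)
  dynamic range;
* planted co-expression modules following a one-factor Gaussian model, so the
  population correlation between two module members equals the configured
  latent correlation; a module may load on a clinical-group indicator to
  plant a trait-associated module;
* planted group-discriminant proteins with a specified log2 fold change in a
  specified subset of fractions;
* fraction/group-exclusive proteins (Venn structure);
* missing-not-at-random detection: logistic dropout on the true intensity.

Generation is a pure function of the configuration (including its seed):
identical configs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from csfpanel.errors import ConfigurationError
from csfpanel.ingest import FRACTIONS, GROUPS, IntensityMatrix

BACKGROUND = "background"


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``latent_correlation`` is the population pairwise correlation between any
    two members (one-factor model).  If ``trait`` is a group name, the shared
    latent factor loads on that group's standardized indicator with weight
    ``trait_strength``, planting a trait-driven module.
    """

    size: int
    latent_correlation: float
    trait: str | None = None
    trait_strength: float = 0.95


@dataclass(frozen=True)
class DESpec:
    """Planted group-discriminant proteins: ``log2_fc`` added to MB samples
    of the listed fractions."""

    n_proteins: int
    log2_fc: float
    fractions: tuple[str, ...] = FRACTIONS


@dataclass(frozen=True)
class SyntheticConfig:
    n_proteins: int = 500
    n_samples_per_cell: int = 3
    module_specs: tuple[ModuleSpec, ...] = (
        ModuleSpec(50, 0.8, trait="MB"),
        ModuleSpec(40, 0.8),
        ModuleSpec(30, 0.8),
    )
    de_specs: tuple[DESpec, ...] = (DESpec(20, 2.0, ("total", "Ex")),)
    exclusive_specs: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {("MB", "Ex"): 5, ("control", "total"): 5}
    )
    baseline_range: tuple[float, float] = (20.0, 30.0)
    dropout_midpoint: float | None = 19.0
    dropout_steepness: float = 0.8
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if self.n_samples_per_cell < 1:
            raise ConfigurationError("n_samples_per_cell must be >= 1")
        for i, m in enumerate(self.module_specs):
            if m.size < 1:
                raise ConfigurationError(f"module_specs[{i}].size must be >= 1")
            if not 0.0 < m.latent_correlation < 1.0:
                raise ConfigurationError(f"module_specs[{i}].latent_correlation must be in (0,1)")
            if m.trait is not None and m.trait not in GROUPS:
                raise ConfigurationError(f"module_specs[{i}].trait must be one of {GROUPS}")
            if not 0.0 <= m.trait_strength <= 1.0:
                raise ConfigurationError(f"module_specs[{i}].trait_strength must be in [0,1]")
        for i, d in enumerate(self.de_specs):
            if d.n_proteins < 0:
                raise ConfigurationError(f"de_specs[{i}].n_proteins must be >= 0")
            bad = set(d.fractions) - set(FRACTIONS)
            if bad:
                raise ConfigurationError(f"de_specs[{i}].fractions contains unknown fractions {sorted(bad)}")
        for (g, f), n in self.exclusive_specs.items():
            if g not in GROUPS or f not in FRACTIONS:
                raise ConfigurationError(f"exclusive_specs key ({g},{f}) is not a valid group x fraction cell")
            if n < 0:
                raise ConfigurationError(f"exclusive_specs[({g},{f})] must be >= 0")
        needed = (
            sum(m.size for m in self.module_specs)
            + sum(d.n_proteins for d in self.de_specs)
            + sum(self.exclusive_specs.values())
        )
        if needed > self.n_proteins:
            raise ConfigurationError(
                f"module_specs + de_specs + exclusive_specs need {needed} proteins, only n_proteins={self.n_proteins} available"
            )
        if self.baseline_range[0] >= self.baseline_range[1]:
            raise ConfigurationError("baseline_range must be increasing")
        if self.dropout_steepness <= 0:
            raise ConfigurationError("dropout_steepness must be > 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Immutable record of what was planted, keyed by protein id."""

    module_assignment: Mapping[str, str]            # protein -> module id or "background"
    de_proteins: Mapping[str, tuple[float, tuple[str, ...]]]  # protein -> (log2 FC, fractions)
    exclusivity: Mapping[str, tuple[str, str]]      # protein -> (group, fraction)
    generator_seed: int

    def module_members(self, module: str) -> list[str]:
        return [p for p, m in self.module_assignment.items() if m == module]


def default_config(**overrides) -> SyntheticConfig:
    """The package's reference study conditions (24 samples, 3 planted
    modules at latent correlation 0.8, 20 discriminant proteins at log2 FC 2)."""
    return replace(SyntheticConfig(), **overrides)


def _sample_frame(n_per_cell: int) -> pd.DataFrame:
    rows = []
    for group in GROUPS:
        for fraction in FRACTIONS:
            for r in range(1, n_per_cell + 1):
                rows.append((f"{group}_{fraction}_{r:02d}", group, fraction))
    return pd.DataFrame(rows, columns=["sample_id", "group", "fraction"]).set_index("sample_id")


def generate_dataset(config: SyntheticConfig) -> tuple[IntensityMatrix, SyntheticTruth]:
    """Generate one dataset and its ground truth from ``config``."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_baseline, rng_factor, rng_noise, rng_dropout = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    annotations = _sample_frame(config.n_samples_per_cell)
    n_samples = len(annotations)
    n = config.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(1, n + 1)]

    lo, hi = config.baseline_range
    baseline = rng_baseline.uniform(lo, hi, size=n)
    noise = rng_noise.normal(0.0, 1.0, size=(n, n_samples))
    x = baseline[:, None] + config.noise_sd * noise

    # layout: [module blocks][DE proteins][exclusive proteins][background]
    cursor = 0
    module_assignment = {p: BACKGROUND for p in protein_ids}
    for mi, spec in enumerate(config.module_specs, start=1):
        members = protein_ids[cursor:cursor + spec.size]
        factor = rng_factor.normal(0.0, 1.0, size=n_samples)
        if spec.trait is not None:
            indicator = (annotations["group"] == spec.trait).to_numpy(dtype=float)
            z = (indicator - indicator.mean()) / indicator.std(ddof=0)
            a = spec.trait_strength
            factor = a * z + math.sqrt(1.0 - a * a) * factor
        rho = spec.latent_correlation
        idx = slice(cursor, cursor + spec.size)
        # replace i.i.d. noise with the one-factor construction at equal total variance
        x[idx] = (
            baseline[idx, None]
            + config.noise_sd * (math.sqrt(rho) * factor[None, :] + math.sqrt(1.0 - rho) * noise[idx])
        )
        for p in members:
            module_assignment[p] = f"planted{mi}"
        cursor += spec.size

    de_proteins: dict[str, tuple[float, tuple[str, ...]]] = {}
    group_arr = annotations["group"].to_numpy()
    fraction_arr = annotations["fraction"].to_numpy()
    for spec in config.de_specs:
        members = protein_ids[cursor:cursor + spec.n_proteins]
        affected_cols = (group_arr == "MB") & np.isin(fraction_arr, list(spec.fractions))
        idx = slice(cursor, cursor + spec.n_proteins)
        x[idx, :] = x[idx, :] + spec.log2_fc * affected_cols[None, :]
        for p in members:
            de_proteins[p] = (spec.log2_fc, tuple(spec.fractions))
        cursor += spec.n_proteins

    exclusivity: dict[str, tuple[str, str]] = {}
    for (group, fraction), count in config.exclusive_specs.items():
        for p in protein_ids[cursor:cursor + count]:
            exclusivity[p] = (group, fraction)
        cursor += count

    if config.dropout_midpoint is None:
        detected = np.ones((n, n_samples), dtype=bool)
    else:
        p_detect = 1.0 / (1.0 + np.exp(-config.dropout_steepness * (x - config.dropout_midpoint)))
        detected = rng_dropout.random((n, n_samples)) < p_detect

    # forced exclusivity overrides dropout
    pid_index = {p: i for i, p in enumerate(protein_ids)}
    for p, (group, fraction) in exclusivity.items():
        cell = (group_arr == group) & (fraction_arr == fraction)
        detected[pid_index[p], :] = cell

    values = pd.DataFrame(np.where(detected, x, np.nan), index=protein_ids, columns=annotations.index)
    matrix = IntensityMatrix(values, annotations)
    truth = SyntheticTruth(
        module_assignment=dict(module_assignment),
        de_proteins=de_proteins,
        exclusivity=exclusivity,
        generator_seed=config.seed,
    )
    return matrix, truth


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write the ground-truth record as a flat TSV."""
    rows = []
    for p, module in truth.module_assignment.items():
        fc, fracs = truth.de_proteins.get(p, (0.0, ()))
        excl = truth.exclusivity.get(p)
        rows.append({
            "protein_id": p,
            "module": module,
            "log2_fc": fc,
            "de_fractions": ",".join(fracs),
            "exclusive_cell": f"{excl[0]}:{excl[1]}" if excl else "",
        })
    pd.DataFrame(rows).set_index("protein_id").to_csv(path, sep="\t")
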
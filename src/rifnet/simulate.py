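"""Synthetic expression datasets with the structure the pipeline assumes.

The generator emulates a 2×2 migrant design: two breeds (Tibetan-like and
Duroc-like) each reared at high and low altitude, ``n_per_group`` animals
per cell (TH, TL, DH, DL).  On the log2 scale it plants

* breed main effects: a constant shift for one breed at both altitudes;
* breed×altitude interaction effects: the same shift applied only in the
  high-altitude cells, giving an interaction of size ``e`` plus a breed
  main effect of ``e/2``;
* genes carrying both effects at full size (``frac_de_both``): the breed
  shift at both altitudes plus the interaction shift in the high-altitude
  cells; these genes appear in both truth sets;
* differentially wired regulators: each wired regulator has a latent
  per-sample signal; its target genes are built as
  ``r*z_reg + sqrt(1-r^2)*noise`` on standardized latents so the expected
  within-group regulator–target correlation is exactly ``r`` (group TH
  uses ``wiring_r_group1``, every other cell ``wiring_r_group2``);
* null regulators: genes on the regulator list with no planted wiring;
* absent probes: drawn from a background distribution truncated at the
  detection threshold, so their flags are "A" in every sample and the
  emitted flags are self-consistent with the detection rule.

Each gene is printed by ``probes_per_gene`` probes sharing the gene's
systematic signal (effects and wiring latent) but carrying independent
residual noise, emulating the probe→gene redundancy of the array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset
from .preprocess import call_detection

__all__ = ["SimConfig", "SimConfigError", "SimTruth", "RecoveryReport",
           "simulate_dataset", "truth_eval", "regulator_ranks"]

BREEDS = ("Tibetan", "Duroc")
ALTITUDES = ("high", "low")
DETECTION_K = 2.0


class SimConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated study.

    Defaults describe a desk-scale version of the migrant design:
    log2-scale baselines around 8 ± 1.5, residual noise 0.5, effect sizes
    of 2 log2 units, two probes per gene, and 8 animals per cell (the real
    study used 2, which makes within-group correlations degenerate; n = 2
    remains allowed).
    """

    n_genes: int = 2000
    probes_per_gene: int = 2
    n_per_group: int = 8
    frac_de_breed: float = 0.05
    frac_de_interaction: float = 0.05
    frac_de_both: float = 0.0
    effect_size_breed: float = 2.0
    effect_size_interaction: float = 2.0
    n_regulators: int = 20
    n_null_regulators: int = 0
    targets_per_regulator: int = 10
    wiring_r_group1: float = 0.9
    wiring_r_group2: float = 0.0
    noise_sd: float = 0.5
    frac_absent: float = 0.05
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    background_mean: float = 3.0
    background_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        def positive(name, strict=True):
            v = getattr(self, name)
            if (v <= 0) if strict else (v < 0):
                raise SimConfigError(f"{name} must be {'positive' if strict else 'non-negative'}, got {v}")

        positive("n_genes")
        positive("probes_per_gene")
        positive("n_per_group")
        for name in ("frac_de_breed", "frac_de_interaction", "frac_de_both", "frac_absent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("wiring_r_group1", "wiring_r_group2"):
            if abs(getattr(self, name)) > 1.0:
                raise SimConfigError(f"{name} must lie in [-1, 1], got {getattr(self, name)}")
        for name in ("n_regulators", "n_null_regulators", "targets_per_regulator"):
            positive(name, strict=False)
        for name in ("noise_sd", "baseline_sd", "background_sd"):
            positive(name, strict=False)
        n_special = (
            self.n_regulators
            + self.n_null_regulators
            + round(self.frac_de_breed * self.n_genes)
            + round(self.frac_de_both * self.n_genes)
            + max(
                round(self.frac_de_interaction * self.n_genes),
                self.n_regulators * self.targets_per_regulator,
            )
        )
        if n_special > self.n_genes:
            raise SimConfigError(
                f"n_genes={self.n_genes} too small for the requested regulators and DE fractions"
            )


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    de_breed_genes: set[str] = field(default_factory=set)
    de_interaction_genes: set[str] = field(default_factory=set)
    regulator_ids: list[str] = field(default_factory=list)
    wired_regulators: list[str] = field(default_factory=list)
    regulator_targets: dict[str, set[str]] = field(default_factory=dict)
    absent_probes: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "de_breed_genes": sorted(self.de_breed_genes),
            "de_interaction_genes": sorted(self.de_interaction_genes),
            "regulator_ids": list(self.regulator_ids),
            "wired_regulators": list(self.wired_regulators),
            "regulator_targets": {k: sorted(v) for k, v in sorted(self.regulator_targets.items())},
            "absent_probes": sorted(self.absent_probes),
        }


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_dataset(config: SimConfig) -> tuple[Dataset, SimTruth, list[str], pd.Series]:
    """Generate one dataset: (Dataset, SimTruth, regulator list, probe annotation).

    Identical configuration (including seed) yields byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    c = config

    genes = _gene_ids(c.n_genes)
    shuffled = list(rng.permutation(genes))
    pos = 0

    def take(k: int) -> list[str]:
        nonlocal pos
        out = shuffled[pos : pos + k]
        pos += k
        return out

    wired = sorted(take(c.n_regulators))
    null_regs = sorted(take(c.n_null_regulators))
    de_breed_only = set(take(round(c.frac_de_breed * c.n_genes)))
    de_inter_only = set(take(round(c.frac_de_interaction * c.n_genes)))
    de_both = set(take(round(c.frac_de_both * c.n_genes)))
    de_breed = de_breed_only | de_both
    de_inter = de_inter_only | de_both
    plain_pool = shuffled[pos:]

    # wired-regulator targets: disjoint across regulators (each target gene is
    # wired to exactly one regulator), drawn from the planted interaction-DE
    # genes first so downstream DE calls overlap them, then unplanted genes
    n_targets_needed = len(wired) * c.targets_per_regulator
    target_pool = list(rng.permutation(sorted(de_inter))) + list(plain_pool)
    if n_targets_needed > len(target_pool):
        raise SimConfigError(
            "targets_per_regulator too large: not enough genes to wire disjoint targets"
        )
    targets: dict[str, set[str]] = {}
    for i, reg in enumerate(wired):
        chunk = target_pool[i * c.targets_per_regulator : (i + 1) * c.targets_per_regulator]
        targets[reg] = set(chunk)
    all_targets = set().union(*targets.values()) if targets else set()

    # samples: TH, TL, DH, DL cells
    sample_ids, breed_col, alt_col = [], [], []
    for breed in BREEDS:
        for alt in ALTITUDES:
            code = breed[0] + alt[0].upper()
            for i in range(1, c.n_per_group + 1):
                sample_ids.append(f"{code}{i}")
                breed_col.append(breed)
                alt_col.append(alt)
    design = pd.DataFrame({"breed": breed_col, "altitude": alt_col},
                          index=pd.Index(sample_ids, name="sample"))
    n_samples = len(sample_ids)
    is_tibetan = np.array([b == "Tibetan" for b in breed_col])
    is_high = np.array([a == "high" for a in alt_col])
    in_th = is_tibetan & is_high

    # per-sample wiring target correlation: TH uses group-1 wiring, the
    # other cells group-2 wiring
    r_per_sample = np.where(in_th, c.wiring_r_group1, c.wiring_r_group2)

    latents = {reg: rng.standard_normal(n_samples) for reg in wired}

    probe_ids: list[str] = []
    probe_gene: list[str] = []
    for g in genes:
        for rplic in range(1, c.probes_per_gene + 1):
            probe_ids.append(f"{g}_p{rplic}")
            probe_gene.append(g)
    n_probes = len(probe_ids)

    # absent probes: only probes of genes without planted structure
    special = set(wired) | set(null_regs) | de_breed | de_inter | all_targets
    eligible = [i for i, g in enumerate(probe_gene) if g not in special]
    n_absent = round(c.frac_absent * n_probes)
    if n_absent > len(eligible):
        raise SimConfigError(
            "frac_absent too large: not enough probes without planted structure"
        )
    absent_idx = set(rng.choice(eligible, size=n_absent, replace=False).tolist()) if n_absent else set()

    target_of: dict[str, str] = {}
    for reg, tgts in targets.items():
        for t in tgts:
            target_of.setdefault(t, reg)  # first wiring assignment wins

    values = np.empty((n_probes, n_samples))
    baseline = rng.normal(c.baseline_mean, c.baseline_sd, size=n_probes)
    detect_threshold = c.background_mean + DETECTION_K * c.background_sd
    upper = (detect_threshold - c.background_mean) / max(c.background_sd, 1e-12)

    effects_cache: dict[str, np.ndarray] = {}

    def effects_for(g: str) -> np.ndarray:
        if g not in effects_cache:
            eff = np.zeros(n_samples)
            if g in de_breed:
                eff += np.where(is_tibetan, c.effect_size_breed, 0.0)
            if g in de_inter:
                eff += np.where(in_th, c.effect_size_interaction, 0.0)
            effects_cache[g] = eff
        return effects_cache[g]

    for i, (pid, g) in enumerate(zip(probe_ids, probe_gene)):
        if i in absent_idx:
            if c.background_sd > 0:
                values[i] = stats.truncnorm.rvs(
                    -np.inf, upper, loc=c.background_mean, scale=c.background_sd,
                    size=n_samples, random_state=rng,
                )
            else:
                values[i] = np.full(n_samples, c.background_mean)
            continue
        if g in latents:
            core = latents[g]
        elif g in target_of:
            reg_latent = latents[target_of[g]]
            eta = rng.standard_normal(n_samples)
            core = r_per_sample * reg_latent + np.sqrt(1.0 - r_per_sample**2) * eta
        else:
            core = rng.standard_normal(n_samples)
        values[i] = baseline[i] + effects_for(g) + c.noise_sd * core

    expression = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe"),
                              columns=sample_ids)
    flags = call_detection(expression, c.background_mean, c.background_sd, k=DETECTION_K)
    annotation = pd.Series(probe_gene, index=expression.index, name="gene")

    tr_list = sorted(wired + null_regs)
    truth = SimTruth(
        de_breed_genes=de_breed,
        de_interaction_genes=de_inter,
        regulator_ids=tr_list,
        wired_regulators=wired,
        regulator_targets=targets,
        absent_probes={probe_ids[i] for i in absent_idx},
    )
    dataset = Dataset(expression=expression, flags=flags, design=design,
                      probe_annotation=annotation)
    return dataset, truth, tr_list, annotation


@dataclass
class RecoveryReport:
    """How well a called gene set recovers a planted truth set.

    ``sensitivity`` is None (undefined) when the truth set is empty.
    """

    n_truth: int
    n_called: int
    n_hit: int
    sensitivity: float | None
    fdp: float


def truth_eval(called: Iterable[str], truth: Iterable[str]) -> RecoveryReport:
    """Sensitivity = |called ∩ truth| / |truth|; FDP = |called \\ truth| / max(1, |called|)."""
    called_set, truth_set = set(called), set(truth)
    hit = len(called_set & truth_set)
    sens = hit / len(truth_set) if truth_set else None
    fdp = len(called_set - truth_set) / max(1, len(called_set))
    return RecoveryReport(
        n_truth=len(truth_set), n_called=len(called_set), n_hit=hit,
        sensitivity=sens, fdp=fdp,
    )


def regulator_ranks(
    rif_table: pd.DataFrame,
    regulators: Iterable[str],
    annotation: pd.Series | None = None,
    column: str = "z1",
) -> dict[str, int]:
    """1-based rank of each planted regulator in the |z| ordering.

    ``rif_table`` is indexed by probe; when ``annotation`` is given the
    planted gene ids are matched through it, otherwise the best rank over
    probes whose id starts with the gene id is used.
    """
    z = rif_table[column].dropna()
    ordered = sorted(z.items(), key=lambda kv: (-abs(kv[1]), str(kv[0])))
    probe_rank = {str(p): i + 1 for i, (p, _) in enumerate(ordered)}
    out: dict[str, int] = {}
    for gene in regulators:
        if annotation is not None:
            probes = annotation.index[annotation == gene]
        else:
            probes = [p for p in probe_rank if p.startswith(str(gene))]
        ranks = [probe_rank[str(p)] for p in probes if str(p) in probe_rank]
        if ranks:
            out[str(gene)] = min(ranks)
    return out
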
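"""Synthetic cohorts with planted TIME structure and ground truth.

The generator emulates the statistical skeleton the downstream analysis
assumes, with every latent quantity recorded so each stage can be checked
against truth:

* three expression-defined TIME subtypes (rich / intermediate / poor) with
  default prevalences 25.4% / 32.9% / 41.7% and graded immune-program
  activity on the immune panel and pathway genes;
* a designated subset of the NK-specific set acts as the planted
  NK-deficiency (NKD) genes: per-patient burden of defective genes is
  Poisson with a subtype-specific mean, elevated in immune-poor subtypes,
  while the remaining NK-specific genes mutate at a subtype-independent
  background rate;
* per-cell-type TIL abundances decrease with burden (and with subtype),
  and marker-gene expression scales with the latent abundance;
* survival is exponential with a log-linear burden effect on the hazard,
  with uniform censoring;
* planted variants are emitted as VCF-style calls with read depths,
  heterozygous/homozygous alt counts constrained to the germline VAF
  windows, and deleteriousness scores in the functional range; noise
  variants carry benign scores and off-window VAFs;
* a control cohort shares the mutation process at a reduced rate, and a
  trial cohort adds a subtype-conditional response label.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gene_sets import TIL_CELL_TYPES, GeneSetCollection
from .germline import HET_HIGH, HET_LOW, HOM_LOW, VariantCall

__all__ = [
    "SUBTYPES",
    "CohortConfig",
    "CohortTruth",
    "Cohort",
    "ControlCohort",
    "TrialCohort",
    "simulate_cohort",
    "simulate_control_cohort",
    "simulate_trial_cohort",
]

SUBTYPES = ("rich", "intermediate", "poor")

# immune-program activity level by subtype index (rich, intermediate, poor)
_LEVELS = np.array([2.0, 1.0, 0.0])


@dataclasses.dataclass
class CohortConfig:
    """Knobs of the generative model (defaults encode the study conditions).

    ``subtype_probs`` follow the reported mean subtype prevalences;
    ``burden_rates`` put at least one defective gene in >60% of patients
    overall; ``log_hazard_per_gene`` is sized so the top/bottom-30% burden
    groups show a hazard ratio near 1.77 under the default burden spread.
    """

    n_samples: int = 600
    subtype_probs: tuple[float, float, float] = (0.254, 0.329, 0.417)
    til_means: tuple[float, float, float] = (0.75, 0.50, 0.30)
    til_noise_sd: float = 0.08
    burden_rates: tuple[float, float, float] = (0.3, 1.7, 2.7)
    burden_til_slope: float = 0.05
    hazard_base: float = 1.0 / 1500.0  # events per day at zero burden
    log_hazard_per_gene: float = 0.17
    censor_horizon: float = 3650.0  # days
    control_rate_factor: float = 0.25
    depth_mean: float = 60.0  # reads
    functional_score_range: tuple[float, float] = (15.0, 40.0)
    benign_score_range: tuple[float, float] = (0.0, 10.0)
    n_nkd_genes: int = 25
    background_burden: float = 0.4
    n_itam_defective: int = 2
    itam_defect_rates: tuple[float, float, float] = (0.02, 0.12, 0.12)
    marker_response: float = 2.2
    subtype_effect_range: tuple[float, float] = (0.7, 2.3)
    ligand_response: float = 0.8  # log-scale ligand expression per latent unit
    ligand_til_effect: float = 0.08  # TIL boost per latent unit at zero burden
    baseline_meanlog: float = 1.0
    baseline_sdlog: float = 0.5
    baseline_gene_sd: float = 1.0  # log-scale spread of per-gene baseline means
    noise_variants_per_sample: float = 3.0
    hom_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if abs(sum(self.subtype_probs) - 1.0) > 1e-12:
            raise ValueError("subtype_probs must sum to 1")
        if any(r < 0 for r in self.burden_rates):
            raise ValueError("burden_rates must be >= 0")
        if not 0 < self.control_rate_factor <= 1:
            raise ValueError("control_rate_factor must be in (0, 1]")
        lo_f, hi_f = self.functional_score_range
        lo_b, hi_b = self.benign_score_range
        if not (lo_f < hi_f and lo_b < hi_b):
            raise ValueError("score ranges must be non-degenerate intervals")
        if max(lo_f, lo_b) < min(hi_f, hi_b):
            raise ValueError("functional and benign score ranges must be disjoint")
        if not 0 <= self.hom_fraction <= 1:
            raise ValueError("hom_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        d = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.items()
        }
        return cls(**d)


@dataclasses.dataclass
class CohortTruth:
    """Latent state of a simulated cohort (the ground truth for tests)."""

    subtype: pd.Series
    burden: pd.Series
    defective_genes: dict[str, list[str]]
    nkd_genes: list[str]
    til_abundance: pd.DataFrame | None = None
    background_genes: dict[str, list[str]] | None = None
    itam_defective_genes: dict[str, list[str]] | None = None
    itam_planted: list[str] | None = None
    response: pd.Series | None = None

    def __post_init__(self) -> None:
        for s, genes in self.defective_genes.items():
            if len(genes) != int(self.burden[s]):
                raise ValueError(f"burden/defective_genes mismatch for sample {s}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subtype": self.subtype.to_dict(),
            "burden": {k: int(v) for k, v in self.burden.items()},
            "defective_genes": self.defective_genes,
            "nkd_genes": self.nkd_genes,
            "background_genes": self.background_genes,
            "itam_defective_genes": self.itam_defective_genes,
            "itam_planted": self.itam_planted,
            "til_abundance": None
            if self.til_abundance is None
            else {
                "index": list(self.til_abundance.index),
                "columns": list(self.til_abundance.columns),
                "values": self.til_abundance.to_numpy().tolist(),
            },
            "response": None if self.response is None else self.response.to_dict(),
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclasses.dataclass
class Cohort:
    expression: pd.DataFrame
    variants: list[VariantCall]
    clinical: pd.DataFrame
    truth: CohortTruth


@dataclasses.dataclass
class ControlCohort:
    variants: list[VariantCall]
    truth: CohortTruth
    samples: list[str]


@dataclasses.dataclass
class TrialCohort:
    expression: pd.DataFrame
    response: pd.Series
    truth: CohortTruth


_REQUIRED_SETS = ("nk_specific", "ligand", "itam", "immune_panel")


def _check_sets(sets: GeneSetCollection, universe: Sequence[str]) -> None:
    pool = set(universe)
    for name in _REQUIRED_SETS:
        if name not in sets:
            raise ValueError(f"gene-set collection lacks required set {name!r}")
        stray = set(sets[name]) - pool
        if stray:
            raise ValueError(
                f"set {name!r} contains genes outside the universe: {sorted(stray)[:5]}"
            )


def _hash_frac(gene: str, salt: str = "") -> float:
    """Deterministic U(0,1)-like value per gene, stable across cohorts."""
    return zlib.crc32(f"{gene}:{salt}".encode("utf-8")) / 2**32


def _norm_ppf(frac: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(min(max(frac, 1e-9), 1 - 1e-9)))


# candidate mid-level responses: early-, linear- and late-activation genes
_SHAPES = (0.15, 0.5, 0.85)


def _gene_response(gene: str, low: float, high: float) -> tuple[float, float]:
    """Per-gene (total log effect, mid-level fraction) for subtype response.

    The total effect is the log-scale expression shift between the poor and
    rich subtypes; the mid-level fraction (strictly inside (0, 1)) places
    the intermediate subtype, so per-gene means stay strictly ordered
    rich > intermediate > poor while response shapes differ across genes.
    """
    delta = low + (high - low) * _hash_frac(gene, "effect")
    shape = _SHAPES[int(_hash_frac(gene, "shape") * len(_SHAPES))]
    return delta, shape


def _simulate_expression(
    rng: np.random.Generator,
    samples: list[str],
    subtype_idx: np.ndarray,
    til_abundance: pd.DataFrame,
    ligand_latent: np.ndarray,
    sets: GeneSetCollection,
    universe: Sequence[str],
    cfg: CohortConfig,
) -> pd.DataFrame:
    n_g, n_s = len(universe), len(samples)
    gene_row = {g: i for i, g in enumerate(universe)}
    # per-gene baseline means (hash-derived, so cohorts share the geometry)
    gene_mean = cfg.baseline_meanlog + cfg.baseline_gene_sd * np.array(
        [_norm_ppf(_hash_frac(g, "baseline")) for g in universe]
    )
    expr = rng.lognormal(
        gene_mean[:, None], cfg.baseline_sdlog, size=(n_g, n_s)
    )

    level = _LEVELS[subtype_idx]  # (n_s,) in {2, 1, 0}
    lo, hi = cfg.subtype_effect_range
    # immune panel and NK-cytotoxicity genes rise with immune activity;
    # Wnt genes rise as activity falls (immune-excluded phenotype)
    up_genes = list(sets["immune_panel"])
    if "pathway_nk_cytotoxicity" in sets:
        up_genes += sets["pathway_nk_cytotoxicity"]
    for genes, levels in ((up_genes, level), (sets.sets.get("pathway_wnt", []), _LEVELS[0] - level)):
        for g in genes:
            delta, shape = _gene_response(g, lo, hi)
            frac = np.choose(levels.astype(int), [0.0, shape, 1.0])
            expr[gene_row[g]] *= np.exp(delta * frac)

    ligand_boost = np.exp(cfg.ligand_response * ligand_latent)
    for g in sets["ligand"]:
        expr[gene_row[g]] *= ligand_boost

    for cell_type in til_abundance.columns:
        marker_set = f"til_{cell_type}"
        if marker_set not in sets:
            continue
        boost = np.exp(cfg.marker_response * til_abundance[cell_type].to_numpy())
        for g in sets[marker_set]:
            expr[gene_row[g]] *= boost
    return pd.DataFrame(expr, index=pd.Index(list(universe), name="gene"), columns=samples)


def _draw_til_abundance(
    rng: np.random.Generator,
    samples: list[str],
    subtype_idx: np.ndarray,
    burden_counts: np.ndarray,
    ligand_latent: np.ndarray,
    cfg: CohortConfig,
) -> pd.DataFrame:
    # ligands of NK-activating receptors recruit TILs only while the
    # receptors are intact: the ligand effect decays exponentially in burden
    ligand_term = cfg.ligand_til_effect * ligand_latent * np.exp(-burden_counts)
    means = (
        np.asarray(cfg.til_means)[subtype_idx]
        - cfg.burden_til_slope * burden_counts
        + ligand_term
    )
    noise = rng.normal(0.0, cfg.til_noise_sd, size=(len(samples), len(TIL_CELL_TYPES)))
    values = np.clip(means[:, None] + noise, 0.0, 1.0)
    return pd.DataFrame(values, index=samples, columns=list(TIL_CELL_TYPES))


def _functional_variant(
    rng: np.random.Generator,
    sample: str,
    gene: str,
    position: int,
    cfg: CohortConfig,
) -> VariantCall:
    depth = max(int(rng.poisson(cfg.depth_mean)), 4)
    if rng.random() < cfg.hom_fraction:
        # homozygous: alt count conditioned into the >90% VAF window
        while True:
            alt = int(rng.binomial(depth, 0.98))
            if alt / depth > HOM_LOW:
                break
    else:
        while True:
            alt = int(rng.binomial(depth, 0.5))
            if HET_LOW <= alt / depth <= HET_HIGH:
                break
    score = float(rng.uniform(*cfg.functional_score_range))
    return VariantCall(
        sample=sample, gene=gene, position=position, depth=depth, alt_depth=alt, score=score
    )


def _noise_variant(
    rng: np.random.Generator,
    sample: str,
    gene: str,
    position: int,
    cfg: CohortConfig,
) -> VariantCall:
    # somatic-like contamination: Beta(2, 8) VAF kept outside both windows
    while True:
        vaf = float(rng.beta(2.0, 8.0))
        if not (HET_LOW <= vaf <= HET_HIGH or vaf > HOM_LOW):
            break
    depth = max(int(rng.poisson(cfg.depth_mean)), 4)
    alt = int(np.clip(rng.binomial(depth, vaf), 0, depth))
    score = float(rng.uniform(*cfg.benign_score_range))
    return VariantCall(
        sample=sample, gene=gene, position=position, depth=depth, alt_depth=alt, score=score
    )


class _PositionCounter:
    """Unique 1-based positions keyed by gene so records never collide."""

    def __init__(self, universe: Sequence[str]) -> None:
        self._row = {g: i for i, g in enumerate(universe)}
        self._used: dict[str, int] = {}

    def next_for(self, gene: str) -> int:
        k = self._used.get(gene, 0)
        self._used[gene] = k + 1
        return self._row[gene] * 1000 + k + 1


def _draw_mutations(
    rng: np.random.Generator,
    samples: list[str],
    rates: np.ndarray,
    nkd_genes: list[str],
    background_pool: list[str],
    positions: _PositionCounter,
    universe: Sequence[str],
    cfg: CohortConfig,
) -> tuple[list[VariantCall], dict[str, list[str]], dict[str, list[str]]]:
    """Draw per-sample defective NKD genes plus background and noise calls.

    ``rates`` is the per-sample Poisson mean of defective NKD genes.
    """
    variants: list[VariantCall] = []
    defective: dict[str, list[str]] = {}
    background: dict[str, list[str]] = {}
    for j, sample in enumerate(samples):
        k = min(int(rng.poisson(rates[j])), len(nkd_genes))
        genes = sorted(rng.choice(nkd_genes, size=k, replace=False)) if k else []
        defective[sample] = [str(g) for g in genes]
        for g in defective[sample]:
            variants.append(
                _functional_variant(rng, sample, g, positions.next_for(g), cfg)
            )
        b = min(int(rng.poisson(cfg.background_burden)), len(background_pool))
        bg = sorted(rng.choice(background_pool, size=b, replace=False)) if b else []
        background[sample] = [str(g) for g in bg]
        for g in background[sample]:
            variants.append(
                _functional_variant(rng, sample, g, positions.next_for(g), cfg)
            )
        n_noise = int(rng.poisson(cfg.noise_variants_per_sample))
        for _ in range(n_noise):
            g = str(universe[int(rng.integers(len(universe)))])
            variants.append(_noise_variant(rng, sample, g, positions.next_for(g), cfg))
    return variants, defective, background


def simulate_cohort(
    config: CohortConfig,
    sets: GeneSetCollection,
    universe: Sequence[str],
) -> Cohort:
    """Simulate the tumor cohort: expression, variant calls, survival, truth."""
    _check_sets(sets, universe)
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    subtype_idx = rng.choice(3, size=n, p=config.subtype_probs)
    nkd_genes = list(sets["nk_specific"][: config.n_nkd_genes])
    background_pool = list(sets["nk_specific"][config.n_nkd_genes :])
    rates = np.asarray(config.burden_rates)[subtype_idx]

    positions = _PositionCounter(universe)
    variants, defective, background = _draw_mutations(
        rng, samples, rates, nkd_genes, background_pool, positions, universe, config
    )
    burden_counts = np.array([len(defective[s]) for s in samples])

    # planted defective ITAM genes, skewed toward immune-poor subtypes
    itam_planted = list(sets["itam"][: config.n_itam_defective])
    itam_defective: dict[str, list[str]] = {s: [] for s in samples}
    itam_rates = np.asarray(config.itam_defect_rates)
    for j, sample in enumerate(samples):
        for g in itam_planted:
            if rng.random() < itam_rates[subtype_idx[j]]:
                itam_defective[sample].append(g)
                variants.append(
                    _functional_variant(rng, sample, g, positions.next_for(g), config)
                )

    ligand_latent = rng.normal(0.0, 1.0, size=n)
    til = _draw_til_abundance(
        rng, samples, subtype_idx, burden_counts, ligand_latent, config
    )
    expression = _simulate_expression(
        rng, samples, subtype_idx, til, ligand_latent, sets, universe, config
    )

    hazard = config.hazard_base * np.exp(config.log_hazard_per_gene * burden_counts)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, config.censor_horizon, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    clinical = pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(samples, name="sample")
    )

    truth = CohortTruth(
        subtype=pd.Series([SUBTYPES[i] for i in subtype_idx], index=samples, name="subtype"),
        burden=pd.Series(burden_counts, index=samples, name="burden"),
        defective_genes=defective,
        nkd_genes=nkd_genes,
        til_abundance=til,
        background_genes=background,
        itam_defective_genes=itam_defective,
        itam_planted=itam_planted,
    )
    return Cohort(expression=expression, variants=variants, clinical=clinical, truth=truth)


def simulate_control_cohort(
    config: CohortConfig,
    sets: GeneSetCollection,
    universe: Sequence[str],
    n_samples: int | None = None,
) -> ControlCohort:
    """Simulate the no-cancer control cohort (mutations only).

    The mutation process is the tumor cohort's subtype-averaged process with
    every rate multiplied by ``control_rate_factor``.
    """
    _check_sets(sets, universe)
    rng = np.random.default_rng([config.seed, 1])
    n = n_samples if n_samples is not None else config.n_samples
    if n < 1:
        raise ValueError("n_samples must be >= 1")
    samples = [f"C{i:04d}" for i in range(n)]
    mean_rate = float(np.dot(config.subtype_probs, config.burden_rates))
    cfg = dataclasses.replace(
        config, background_burden=config.background_burden * config.control_rate_factor
    )
    rates = np.full(n, mean_rate * config.control_rate_factor)
    nkd_genes = list(sets["nk_specific"][: config.n_nkd_genes])
    background_pool = list(sets["nk_specific"][config.n_nkd_genes :])
    positions = _PositionCounter(universe)
    variants, defective, background = _draw_mutations(
        rng, samples, rates, nkd_genes, background_pool, positions, universe, cfg
    )
    burden_counts = np.array([len(defective[s]) for s in samples])
    truth = CohortTruth(
        subtype=pd.Series("none", index=samples, name="subtype"),
        burden=pd.Series(burden_counts, index=samples, name="burden"),
        defective_genes=defective,
        nkd_genes=nkd_genes,
        background_genes=background,
    )
    return ControlCohort(variants=variants, truth=truth, samples=samples)


def simulate_trial_cohort(
    config: CohortConfig,
    sets: GeneSetCollection,
    universe: Sequence[str],
    n: int,
    p_response_given_rich: float = 0.6,
    p_response_given_other: float = 0.12,
) -> TrialCohort:
    """Simulate an immunotherapy-trial cohort: expression plus response labels.

    Response is Bernoulli conditional on the latent subtype, enriched in the
    TIME-rich subtype by default.
    """
    _check_sets(sets, universe)
    if n < 1:
        raise ValueError("n must be >= 1")
    for p in (p_response_given_rich, p_response_given_other):
        if not 0.0 <= p <= 1.0:
            raise ValueError("response probabilities must be in [0, 1]")
    rng = np.random.default_rng([config.seed, 2])
    samples = [f"T{i:04d}" for i in range(n)]
    subtype_idx = rng.choice(3, size=n, p=config.subtype_probs)
    nkd_genes = list(sets["nk_specific"][: config.n_nkd_genes])
    rates = np.asarray(config.burden_rates)[subtype_idx]
    k = np.minimum(rng.poisson(rates), len(nkd_genes))
    defective = {
        s: sorted(str(g) for g in rng.choice(nkd_genes, size=int(k[j]), replace=False))
        for j, s in enumerate(samples)
    }
    ligand_latent = rng.normal(0.0, 1.0, size=n)
    til = _draw_til_abundance(rng, samples, subtype_idx, k, ligand_latent, config)
    expression = _simulate_expression(
        rng, samples, subtype_idx, til, ligand_latent, sets, universe, config
    )
    p_resp = np.where(subtype_idx == 0, p_response_given_rich, p_response_given_other)
    response = pd.Series(
        (rng.random(n) < p_resp).astype(int), index=samples, name="response"
    )
    truth = CohortTruth(
        subtype=pd.Series([SUBTYPES[i] for i in subtype_idx], index=samples, name="subtype"),
        burden=pd.Series(k.astype(int), index=samples, name="burden"),
        defective_genes=defective,
        nkd_genes=nkd_genes,
        til_abundance=til,
        response=response,
    )
    return TrialCohort(expression=expression, response=response, truth=truth)
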
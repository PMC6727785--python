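"""End-to-end pipeline: simulate -> filter -> subtype -> deconvolve ->
discover -> associate, with a JSON manifest describing every run.

All randomness flows from one global seed through stable per-stage derived
seeds, so a re-run with the same config reproduces byte-identical outputs
and any stage can be reproduced in isolation from the manifest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._utils import derive_seed
from .gene_sets import (
    GeneSetCollection,
    make_fixture_universe,
    read_clinical,
    read_expression,
    read_gmt,
    write_clinical,
    write_expression,
    write_gmt,
)
from .germline import (
    build_mutation_matrix,
    burden,
    read_vcf,
    write_mutation_matrix,
    write_vcf,
)
from .discovery import (
    combine_with_itam,
    differential_mutation_test,
    identify_potential_nkd,
)
from .simulate import (
    CohortConfig,
    simulate_cohort,
    simulate_control_cohort,
    simulate_trial_cohort,
)
from .stats import (
    burden_til_correlation,
    case_control_test,
    fisher_subtype_enrichment,
    hypergeom_enrichment,
    ligand_stratification,
    logrank_test,
    randomization_test,
    split_quantile_groups,
)
from .subtypes import cluster_time_subtypes, knn_assign, signature_genes
from .til import til_profile

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Parameters of a full pipeline run (defaults match module defaults)."""

    out_dir: str = "nktime_run"
    seed: int = 1
    simulate: bool = True
    n_samples: int = 600
    n_control: int = 600
    n_trial: int = 100
    n_genes: int = 6000
    score_threshold: float = 15.0
    q_max: float = 0.05
    top_frac: float = 0.30
    bottom_frac: float = 0.30
    ligand_tail_frac: float = 0.10
    knn_k: int = 5
    ssgsea_alpha: float = 0.25
    n_perm: int = 200
    # external inputs, used when simulate is False
    expression_path: str | None = None
    vcf_path: str | None = None
    control_vcf_path: str | None = None
    clinical_path: str | None = None
    gmt_path: str | None = None
    trial_expression_path: str | None = None
    cohort: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
                fh.write("\n")
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"no {what} path given and simulate is off")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} file not found: {p}")
    return p


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = {
        stage: derive_seed(config.seed, stage)
        for stage in ("simulate", "randomization")
    }
    outputs: list[str] = []
    notes: dict[str, str] = {}

    def save(name: str) -> Path:
        outputs.append(name)
        return out / name

    # ------------------------------------------------------------------ inputs
    if config.simulate:
        sets, universe = make_fixture_universe(config.n_genes, seed=stage_seeds["simulate"])
        cohort_cfg = CohortConfig.from_dict(
            {
                "n_samples": config.n_samples,
                "seed": stage_seeds["simulate"],
                **config.cohort,
            }
        )
        cohort = simulate_cohort(cohort_cfg, sets, universe)
        control = simulate_control_cohort(cohort_cfg, sets, universe, config.n_control)
        trial = simulate_trial_cohort(cohort_cfg, sets, universe, config.n_trial)
        write_gmt(sets, save("gene_sets.gmt"))
        (save("universe.txt")).write_text("\n".join(universe) + "\n", encoding="utf-8")
        write_expression(cohort.expression, save("expression.tsv"))
        write_vcf(cohort.variants, list(cohort.expression.columns), save("variants.vcf"))
        write_vcf(control.variants, control.samples, save("control_variants.vcf"))
        write_clinical(cohort.clinical, save("clinical.tsv"))
        write_expression(trial.expression, save("trial_expression.tsv"))
        trial.response.to_frame().to_csv(
            save("trial_response.tsv"), sep="\t", index_label="sample", lineterminator="\n"
        )
        cohort.truth.to_json(save("truth.json"))
        expression = cohort.expression
        clinical = cohort.clinical
        calls = cohort.variants
        control_calls = control.variants
        control_samples = control.samples
        trial_expression = trial.expression
        trial_response = trial.response
    else:
        gmt = _require(config.gmt_path, "gene-set GMT")
        sets = read_gmt(gmt)
        expression = read_expression(_require(config.expression_path, "expression"))
        clinical = read_clinical(_require(config.clinical_path, "clinical"))
        calls = read_vcf(_require(config.vcf_path, "VCF"))
        universe = list(expression.index)
        control_calls = None
        control_samples = None
        if config.control_vcf_path is not None:
            control_calls = read_vcf(_require(config.control_vcf_path, "control VCF"))
            control_samples = sorted({c.sample for c in control_calls})
        trial_expression = None
        trial_response = None
        if config.trial_expression_path is not None:
            trial_expression = read_expression(
                _require(config.trial_expression_path, "trial expression")
            )

    samples = list(expression.columns)

    # ------------------------------------------------------------------ filter
    matrix = build_mutation_matrix(calls, universe, samples, config.score_threshold)
    write_mutation_matrix(matrix, save("mutation_matrix.tsv"))
    control_matrix = None
    if control_calls is not None:
        control_matrix = build_mutation_matrix(
            control_calls, universe, control_samples, config.score_threshold
        )
        write_mutation_matrix(control_matrix, save("control_matrix.tsv"))

    # ----------------------------------------------------------------- subtype
    assignment = cluster_time_subtypes(expression, sets["immune_panel"])
    assignment.to_frame().to_csv(save("assignment.tsv"), sep="\t", lineterminator="\n")
    pathway_sets = sets.subset("pathway_")
    signature = signature_genes(expression, assignment, pathway_sets, q_max=config.q_max)
    signature.to_csv(save("signature.tsv"), sep="\t", index=False, lineterminator="\n")

    # ------------------------------------------------------------------ deconv
    marker_sets = sets.subset("til_")
    profile = til_profile(expression, marker_sets, alpha=config.ssgsea_alpha)
    profile.to_csv(save("til_profile.tsv"), sep="\t", lineterminator="\n")

    # ---------------------------------------------------------------- discover
    nkd_report = differential_mutation_test(matrix, assignment, sets["nk_specific"])
    nkd_report.to_csv(save("nkd_report.tsv"), sep="\t", index=False, lineterminator="\n")
    potential = identify_potential_nkd(
        matrix, expression, assignment, sets["nk_specific"], q_max=config.q_max
    )
    combined = combine_with_itam(
        potential, sets["itam"] if "itam" in sets else [], matrix, assignment,
        q_max=config.q_max,
    )
    combined.to_csv(save("nkd_genes.tsv"), sep="\t", index=False, lineterminator="\n")
    candidate_genes = list(combined["gene"])
    if not candidate_genes:
        notes["burden_gene_source"] = "nk_specific (no candidate passed discovery)"
        candidate_genes = list(sets["nk_specific"])
    else:
        notes["burden_gene_source"] = "discovered candidates"

    # ------------------------------------------------------------------- assoc
    sample_burden = burden(matrix, candidate_genes)
    sample_burden.to_frame().to_csv(
        save("burden.tsv"), sep="\t", index_label="sample", lineterminator="\n"
    )
    groups = split_quantile_groups(
        sample_burden, top_frac=config.top_frac, bottom_frac=config.bottom_frac
    )
    surv = logrank_test(clinical, groups)
    with open(save("survival.json"), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(
            {
                "n_high": surv.n1,
                "n_low": surv.n2,
                "observed_high": surv.observed1,
                "expected_high": surv.expected1,
                "observed_low": surv.observed2,
                "expected_low": surv.expected2,
                "variance": surv.variance,
                "chi2": surv.chi2,
                "p": surv.p,
                "hazard_ratio_oe": surv.hazard_ratio,
                "hr_ci": list(surv.hr_ci),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")

    correlation = burden_til_correlation(sample_burden, profile)
    correlation.to_csv(save("correlation.tsv"), sep="\t", index=False, lineterminator="\n")

    ligand = ligand_stratification(
        sample_burden,
        expression,
        sets["ligand"],
        profile,
        bottom_frac=config.ligand_tail_frac,
        top_frac=config.ligand_tail_frac,
    )
    ligand.to_csv(save("ligand.tsv"), sep="\t", index=False, lineterminator="\n")

    fisher_rows = []
    for gene in combined["gene"]:
        res = fisher_subtype_enrichment(matrix, assignment, gene)
        fisher_rows.append({"gene": gene, **res})
    pd.DataFrame(fisher_rows, columns=["gene", "odds_ratio", "p"]).to_csv(
        save("fisher.tsv"), sep="\t", index=False, lineterminator="\n"
    )

    if control_matrix is not None:
        cc = case_control_test(matrix, control_matrix, candidate_genes)
        cc.to_csv(save("case_control.tsv"), sep="\t", index=False, lineterminator="\n")

    rnd_universe = list(sets["nk_specific"])
    if "itam" in sets:
        rnd_universe += [g for g in sets["itam"] if g not in set(rnd_universe)]
    rnd = randomization_test(
        matrix,
        profile,
        clinical,
        candidate_genes,
        rnd_universe,
        n_perm=config.n_perm,
        seed=stage_seeds["randomization"],
    )
    with open(save("randomization.json"), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(
            {
                "observed": rnd["observed"],
                "p": rnd["p"],
                "n_perm": config.n_perm,
                "statistic": rnd["statistic"],
                "null_mean": float(rnd["null"].mean()),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")

    if len(signature):
        enrich = hypergeom_enrichment(
            list(signature["gene"]), pathway_sets, list(expression.index)
        )
        enrich.to_csv(
            save("pathway_enrichment.tsv"), sep="\t", index=False, lineterminator="\n"
        )

    if trial_expression is not None and len(signature):
        assigned = knn_assign(
            trial_expression, expression, assignment, signature, k=config.knn_k
        )
        assigned.to_frame().to_csv(
            save("trial_assignment.tsv"), sep="\t", index_label="sample",
            lineterminator="\n",
        )
        if trial_response is not None:
            is_rich = assigned == "rich"
            resp = trial_response.loc[assigned.index].astype(bool)
            table = [
                [int((is_rich & resp).sum()), int((is_rich & ~resp).sum())],
                [int((~is_rich & resp).sum()), int((~is_rich & ~resp).sum())],
            ]
            from scipy.stats import fisher_exact

            _, p = fisher_exact(table, alternative="two-sided")
            n_resp = int(resp.sum())
            with open(save("trial_response.json"), "w", encoding="utf-8", newline="\n") as fh:
                json.dump(
                    {
                        "responders_rich": table[0][0],
                        "nonresponders_rich": table[0][1],
                        "responders_other": table[1][0],
                        "nonresponders_other": table[1][1],
                        "responder_rich_fraction": (table[0][0] / n_resp) if n_resp else None,
                        "fisher_p": float(p),
                    },
                    fh,
                    indent=1,
                    sort_keys=True,
                )
                fh.write("\n")

    manifest = {
        "package": "nktime",
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": stage_seeds,
        "notes": notes,
        "outputs": sorted(outputs + ["manifest.json"]),
    }
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
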
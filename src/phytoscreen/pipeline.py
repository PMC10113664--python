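"""End-to-end screening pipeline on synthetic inputs.

Runs the full chain: EMR mining (core drugs + symptom communities) ->
interactome + RWR labelling -> compound features -> KNN screen with ROC
thresholding -> per-drug effective counts -> Ward clustering formula
selection -> enrichment of the selected targets -> cohort statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as ch
from . import enrich as en
from . import features as ft
from . import interactome as ia
from . import network as nw
from . import screen as sc
from .synthdata import SynthConfig, simulate_cohort, simulate_emr, simulate_knowledge_base

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    selected_drugs: list
    formula_p: float
    screen: sc.ScreenResults
    module_aucs: dict
    counts: pd.DataFrame
    fractions: pd.DataFrame
    core_drugs: list
    rr_table: pd.DataFrame
    communities: nw.CommunityPartition
    truth_effective_drugs: list
    truth_auc: float
    cohort_stats: dict = field(default_factory=dict)
    enrichment: pd.DataFrame | None = None
    complexes: list = field(default_factory=list)

    @property
    def recovered(self) -> bool:
        return set(self.selected_drugs) == set(self.truth_effective_drugs)

    def summary(self) -> str:
        lines = [
            "Botanical formula screening pipeline",
            f"  core drugs (network extraction): {', '.join(self.core_drugs)}",
            f"  symptom communities: {self.communities.n_communities} "
            f"(Q = {self.communities.q:.3f})",
            self.screen.summary(),
            f"  OOF AUC vs planted truth: {self.truth_auc:.3f}",
            "  per-module AUCs: "
            + ", ".join(f"{m}={a:.3f}" for m, a in self.module_aucs.items()),
            f"  selected formula ({len(self.selected_drugs)} drugs, "
            f"p = {self.formula_p:.4f}): {', '.join(self.selected_drugs)}",
            f"  planted effective drugs: {', '.join(self.truth_effective_drugs)}",
        ]
        if self.cohort_stats:
            cs = self.cohort_stats
            lines.append(
                f"  cohort IPTW OR = {cs['iptw_or']:.3f} "
                f"(95% CI {cs['iptw_or_ci'][0]:.3f}-{cs['iptw_or_ci'][1]:.3f}); "
                f"naive OR = {cs['naive_or']:.3f}; "
                f"max post-weighting SMD = {cs['max_smd_after']:.3f}"
            )
        return "\n".join(lines)


def _screen_with_labels(table, labels, cfg):
    t = table.copy()
    t["label"] = labels
    return sc.ScreenModel(t, cfg).fit()


def run_pipeline(
    cfg: SynthConfig | None = None,
    seed: int = 0,
    knn: sc.KNNConfig | None = None,
    with_baselines: bool = False,
    with_cohort: bool = True,
    with_enrichment: bool = True,
    label_quantile: float = 0.75,
    n_permutations: int = 10_000,
    outdir=None,
) -> PipelineResult:
    """Run the whole screening chain on synthetic inputs.

    ``label_quantile`` sets the RWR-relevance quantile above which a
    compound is labelled an effective candidate for classifier training.
    The pipeline default keeps the top quartile: a quartile *floor*
    (labelling 75% of compounds positive) is incompatible with a
    selective screen in which roughly a fifth of compounds are planted
    as effective, and makes the downstream per-drug counts mostly noise.
    The bare :func:`~phytoscreen.interactome.label_compounds` operation
    keeps the floor convention and both are configurable.
    """
    cfg = cfg or SynthConfig()
    knn = knn or sc.KNNConfig(seed=seed)
    rng = np.random.default_rng(seed)

    # 1. EMR mining: co-prescription core + high-RR drugs
    emr = simulate_emr(cfg, seed=seed)
    case_records = [r for r in emr.prescriptions if r.is_target_disease]
    drug_net = nw.build_cooccurrence_network(case_records)
    core_res = nw.extract_core_drugs(drug_net)
    core_drugs = core_res.top(cfg.n_core_drugs)
    remaining = [d for d in drug_net.nodes if d not in core_drugs]
    rr_rows = []
    for d in remaining:
        r = nw.drug_relative_risk(emr.prescriptions, d)
        rr_rows.append({"drug": d, "rr": r.rr, "p": r.p,
                        "ci_low": r.ci_low, "ci_high": r.ci_high})
    rr_table = (
        pd.DataFrame(rr_rows).sort_values("rr", ascending=False).reset_index(drop=True)
    )
    rr_sel = rr_table[rr_table["p"] < 0.05].head(cfg.n_rr_drugs)["drug"].tolist()
    mined_drugs = list(core_drugs) + rr_sel

    # 2. symptom communities
    sym_net = nw.build_cooccurrence_network(emr.symptoms)
    communities = nw.louvain_communities(sym_net, seed=seed)

    # 3. knowledge base for the mined drugs; interactome + RWR labelling
    kb = simulate_knowledge_base(cfg, seed=seed)
    kb_drugs = [d for d in mined_drugs if d in set(kb.drugs)] or kb.drugs
    drug_compounds = {d: kb.drug_compounds[d] for d in kb_drugs}
    compound_targets = {
        c: kb.compound_targets[c] for ids in drug_compounds.values() for c in ids
    }
    node_sets = [kb.disease_genes, *kb.community_genes.values(),
                 *compound_targets.values()]
    net = ia.assemble_interactome(kb.interactome_edges, node_sets, min_confidence=700)
    rwr = ia.random_walk_restart(net, kb.disease_genes)
    rel = ia.compound_relevance(rwr, compound_targets)
    labelled, threshold = ia.label_compounds(rel, quantile_q=label_quantile)
    labels = {l.compound_id: l.label for l in labelled}

    # 4. features (one Wang/BMA scorer shared by all reference sets)
    dag = ft.OntologyDAG.from_frame(kb.ontology_edges)
    scorer = ft.GoSimScorer(kb.annotations, dag)
    reference_sets = [kb.disease_genes, *kb.community_genes.values()]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = ft.build_feature_table(
            kb.ob_table, compound_targets, reference_sets, kb.annotations,
            dag, kb.community_genes, labels, scorer=scorer,
        )

    # 5. disease-level screen + per-module screens (same pipeline with the
    # module's gene set as reference for RWR labels, jac and gosim)
    screen = sc.ScreenModel(table, knn).fit(with_baselines=with_baselines)
    calls = {"overall": screen.effective_calls().to_dict()}
    module_aucs = {}
    for m in sorted(kb.community_genes):
        mset = kb.community_genes[m]
        # module relevance is anchored to the disease: seeds are the
        # disease genes together with the community's genes
        rwr_m = ia.random_walk_restart(net, set(mset) | kb.disease_genes)
        rel_m = ia.compound_relevance(rwr_m, compound_targets)
        lab_m, _ = ia.label_compounds(rel_m, quantile_q=label_quantile)
        table_m = pd.DataFrame(
            {
                "ob": table["ob"],
                "jac": [ft.jaccard(compound_targets[c], mset) for c in table.index],
                "gosim": [
                    scorer.geneset_sim(compound_targets[c], mset)
                    for c in table.index
                ],
                "man": table["man"],
            },
            index=table.index,
        ).fillna(0.0)
        res_m = _screen_with_labels(
            table_m,
            pd.Series({l.compound_id: l.label for l in lab_m}).reindex(table.index),
            knn,
        )
        module_aucs[m] = res_m.auc
        calls[m] = res_m.effective_calls().to_dict()

    # order columns modules first, overall last (selection uses the last column)
    ordered = {m: calls[m] for m in sorted(kb.community_genes)}
    ordered["overall"] = calls["overall"]
    counts = sc.effective_counts(ordered, drug_compounds)
    n_comp = pd.Series({d: len(c) for d, c in drug_compounds.items()})
    fractions = counts.div(n_comp, axis=0)

    # 6. formula selection: Ward on per-drug effective fractions
    dendro = sc.ward_cluster(counts, row_totals=n_comp)
    formula = sc.select_formula(
        dendro, fractions, n_clusters=2,
        n_permutations=n_permutations, seed=seed,
    )

    # truth-level diagnostics
    truth = kb.truth_labels().reindex(table.index)
    truth_auc = (
        sc.roc_auc(truth.to_numpy(), screen.oof_scores.to_numpy()).auc
        if truth.nunique() == 2 else float("nan")
    )

    # 7. enrichment + complexes on the effective compounds' targets
    enrichment = None
    complexes = []
    if with_enrichment:
        eff_comps = [c for c, v in calls["overall"].items() if v]
        eff_targets = set().union(*(compound_targets[c] for c in eff_comps)) \
            if eff_comps else set()
        if eff_targets:
            gene_sets = {"disease": kb.disease_genes, **kb.community_genes}
            enrichment = en.hypergeom_ora(
                eff_targets & set(net.nodes), gene_sets, set(net.nodes)
            )
            dist = ia.shortest_path_lengths(net, kb.disease_genes & set(net.nodes))
            strong = ia.strongly_connected_nodes(dist) & eff_targets
            if strong:
                complexes = en.mcode(net.subgraph(strong))

    # 8. cohort validation
    cohort_stats = {}
    if with_cohort:
        frame = simulate_cohort(cfg, seed=seed)
        frame = frame.assign(log_scr=np.log(frame["scr"]))
        covs = ["age", "sex_male", "stay_days", "log_scr"]
        scores = ch.propensity_scores(frame, covs)
        weights = ch.iptw_weights(scores, frame["treated"].to_numpy(bool))
        bal = ch.balance_table(frame, covs, weights=weights)
        iptw = ch.weighted_logistic_or(frame["improved"], frame["treated"], weights)
        naive = ch.weighted_logistic_or(
            frame["improved"], frame["treated"], np.ones(len(frame))
        )
        cohort_stats = {
            "iptw_or": iptw["or"],
            "iptw_or_ci": iptw["or_ci"],
            "naive_or": naive["or"],
            "max_smd_after": float(bal["smd_after"].max()),
            "max_smd_before": float(bal["smd_before"].max()),
            "balance": bal,
            "planted_or": cfg.treatment_or,
        }

    result = PipelineResult(
        selected_drugs=formula["drugs"],
        formula_p=formula["p_value"],
        screen=screen,
        module_aucs=module_aucs,
        counts=counts,
        fractions=fractions,
        core_drugs=list(core_drugs),
        rr_table=rr_table,
        communities=communities,
        truth_effective_drugs=sorted(kb.effective_drugs),
        truth_auc=truth_auc,
        cohort_stats=cohort_stats,
        enrichment=enrichment,
        complexes=complexes,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.screen.oof_scores.to_csv(outdir / "oof_scores.csv")
    roc = result.screen.roc
    pd.DataFrame(
        {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
    ).to_csv(outdir / "roc.csv", index=False)
    (outdir / "auc.json").write_text(json.dumps(
        {"knn": roc.auc, "modules": result.module_aucs,
         "baselines": result.screen.baseline_aucs}, indent=2))
    result.counts.to_csv(outdir / "counts.tsv", sep="\t")
    (outdir / "formula.json").write_text(json.dumps(
        {"drugs": result.selected_drugs, "p_value": result.formula_p,
         "planted": result.truth_effective_drugs}, indent=2))
    if result.enrichment is not None:
        result.enrichment.to_csv(outdir / "enrichment.csv", index=False)
    (outdir / "summary.txt").write_text(result.summary() + "\n")
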
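"""Seeded generators for every pipeline input, with planted ground truth.

Three generators emulate the shapes of the real sources so the whole
pipeline runs without any download:

* ``simulate_emr`` — prescription and symptom records with a planted
  co-prescription core, planted high-relative-risk drugs and planted
  symptom communities (stochastic-block structure);
* ``simulate_knowledge_base`` — a drug-compound-target knowledge base, a
  modular interactome with a disease module, a small ontology DAG with
  gene annotations, community gene sets and oral-bioavailability values,
  with a planted subset of disease-proximal "effective" compounds;
* ``simulate_cohort`` — a confounded two-arm retrospective cohort with a
  planted treatment effect on the odds scale.

Every generator is deterministic given its seed, and the planted truth
is returned alongside the data so downstream stages can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .network import PrescriptionRecord, SymptomRecord

__all__ = ["SynthConfig", "KnowledgeBase", "EMRData",
           "simulate_knowledge_base", "simulate_emr", "simulate_cohort"]


@dataclass
class SynthConfig:
    """Study-condition parameters for the synthetic generators.

    The default sizes mirror the real study's scale: 2,055 case
    patients, 14 candidate botanical drugs of which 7 form the planted
    effective formula, five main symptom communities, and cohort arms of
    286 treated / 279 control eligible patients.
    """

    # knowledge base
    n_drugs: int = 14
    n_effective_drugs: int = 7
    compounds_per_drug: tuple = (20, 80)  # uniform inclusive range
    effective_compound_rate: float = 0.4    # within effective drugs
    background_compound_rate: float = 0.05  # within other drugs
    targets_per_compound: tuple = (3, 12)
    n_genes: int = 500
    n_communities: int = 5
    disease_module_size: int = 40
    community_set_size: int = 35
    background_density: float = 0.02
    module_density: float = 0.3
    # disease-module <-> symptom-community interaction density in the
    # PPI network (0 keeps the blocks linked only through the background)
    disease_community_density: float = 0.0
    ob_effective: tuple = (45.0, 10.0)  # mean, sd (percent), truncated >= 0
    ob_other: tuple = (25.0, 10.0)
    # target-origin mixtures (module, community, background)
    effective_target_mix: tuple = (0.5, 0.3, 0.2)
    background_target_mix: tuple = (0.0, 0.15, 0.85)
    # each compound regulates mainly one "home" symptom community
    compound_home_affinity: float = 0.8

    # EMR
    n_patients: int = 2055          # case (target-disease) patients
    n_control_patients: int = 2000  # other hypertension patients
    n_core_drugs: int = 9
    n_rr_drugs: int = 5
    n_background_drugs: int = 46
    core_coprescription_rate: float = 0.6
    core_rate_control: float = 0.15
    rr_drug_rate_case: float = 0.25
    rr_drug_rate_control: float = 0.05
    background_drug_rate: float = 0.08
    n_symptoms_per_community: int = 12
    symptoms_per_patient: tuple = (3, 7)
    symptom_home_affinity: float = 0.8

    # cohort
    n_eligible_treated: int = 286
    n_eligible_control: int = 279
    treatment_or: float = 2.5
    control_improve_rate: float = 0.35
    # per-sd shifts of treated covariate means (confounding: treated healthier)
    confounder_shift: dict = field(default_factory=lambda: {
        "age": -0.35, "log_scr": -0.45, "stay_days": -0.2})
    # per-sd covariate effects on the improvement log-odds
    outcome_effects: dict = field(default_factory=lambda: {
        "age": -0.35, "log_scr": -0.45, "stay_days": -0.15, "sex_male": 0.15})


@dataclass
class KnowledgeBase:
    drugs: list
    drug_compounds: dict           # drug -> [compound ids]
    compound_targets: dict         # compound -> set of genes
    ob_table: pd.DataFrame         # compound_id, ob_percent
    interactome_edges: pd.DataFrame  # protein_a, protein_b, combined_score
    ontology_edges: pd.DataFrame   # child, parent, relation
    annotations: dict              # gene -> [terms]
    disease_genes: set
    community_genes: dict          # community name -> gene set
    effective_drugs: set           # planted truth
    effective_compounds: set       # planted truth

    @property
    def all_compounds(self) -> list:
        return sorted(self.compound_targets)

    def truth_labels(self) -> pd.Series:
        comps = self.all_compounds
        return pd.Series(
            [int(c in self.effective_compounds) for c in comps],
            index=comps, name="truth",
        )


@dataclass
class EMRData:
    prescriptions: list    # PrescriptionRecord
    symptoms: list         # SymptomRecord
    core_drugs: list       # planted co-prescription core
    rr_drugs: list         # planted high-RR drugs
    symptom_blocks: dict   # symptom -> planted community index


def _gene_names(n: int) -> list:
    return [f"G{i:04d}" for i in range(n)]


def simulate_knowledge_base(cfg: SynthConfig, seed: int = 0) -> KnowledgeBase:
    """Drug-compound-target knowledge base with a planted effective subset.

    Effective compounds draw their targets preferentially from the
    disease module (and, secondarily, the symptom-community gene sets)
    and carry higher oral bioavailability, so all four downstream
    features separate the classes by construction.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_names(cfg.n_genes)
    need = cfg.disease_module_size + cfg.n_communities * cfg.community_set_size
    if need > cfg.n_genes:
        raise ValueError("gene universe too small for module + community sets")

    disease = genes[: cfg.disease_module_size]
    community_genes = {}
    pos = cfg.disease_module_size
    for m in range(cfg.n_communities):
        community_genes[f"M{m}"] = set(genes[pos: pos + cfg.community_set_size])
        pos += cfg.community_set_size
    background = genes[pos:]
    comm_pool = sorted(set().union(*community_genes.values()))

    # drugs / compounds / targets / OB
    drugs = [f"H{i + 1:02d}" for i in range(cfg.n_drugs)]
    effective_drugs = set(rng.choice(drugs, size=cfg.n_effective_drugs,
                                     replace=False))
    drug_compounds: dict = {}
    compound_targets: dict = {}
    effective_compounds: set = set()
    ob_rows = []
    lo, hi = cfg.compounds_per_drug
    t_lo, t_hi = cfg.targets_per_compound
    comm_lists = [sorted(community_genes[f"M{m}"]) for m in range(cfg.n_communities)]
    pools = (disease, comm_pool, background)
    for drug in drugs:
        n_c = int(rng.integers(lo, hi + 1))
        rate = (cfg.effective_compound_rate if drug in effective_drugs
                else cfg.background_compound_rate)
        # the planted rate holds exactly per drug so the drug-level truth
        # is unambiguous (not a Bernoulli realization)
        n_eff = int(round(rate * n_c))
        eff_slots = set(rng.choice(n_c, size=n_eff, replace=False))
        ids = []
        for j in range(n_c):
            cid = f"{drug}_c{j + 1:03d}"
            ids.append(cid)
            eff = j in eff_slots
            mix = (cfg.effective_target_mix if eff
                   else cfg.background_target_mix)
            home = comm_lists[int(rng.integers(cfg.n_communities))]
            n_t = int(rng.integers(t_lo, t_hi + 1))
            origin = rng.choice(3, size=n_t, p=mix)
            targets = set()
            for o in origin:
                if o == 1 and rng.random() < cfg.compound_home_affinity:
                    targets.add(home[int(rng.integers(len(home)))])
                else:
                    targets.add(pools[o][int(rng.integers(len(pools[o])))])
            compound_targets[cid] = targets
            if eff:
                effective_compounds.add(cid)
            mu, sd = cfg.ob_effective if eff else cfg.ob_other
            ob_rows.append((cid, max(0.0, float(rng.normal(mu, sd)))))
        drug_compounds[drug] = ids
    ob_table = pd.DataFrame(ob_rows, columns=["compound_id", "ob_percent"])

    # modular interactome: dense blocks (disease module + community sets)
    # over a sparse background, STRING-style integer confidences
    blocks = [sorted(disease)] + [sorted(s) for s in community_genes.values()]
    idx = {g: i for i, g in enumerate(genes)}
    n = cfg.n_genes
    upper = np.triu(rng.random((n, n)) < cfg.background_density, k=1)
    for block in blocks:
        bi = np.array([idx[g] for g in block])
        sub = np.triu(
            rng.random((len(bi), len(bi))) < cfg.module_density, k=1
        )
        upper[np.ix_(bi, bi)] |= sub
    di = np.array([idx[g] for g in blocks[0]])  # disease module
    for block in blocks[1:]:
        bi = np.array([idx[g] for g in block])
        cross = rng.random((len(di), len(bi))) < cfg.disease_community_density
        # keep the matrix upper-triangular (disease indices precede others)
        upper[np.ix_(di, bi)] |= cross
    a_idx, b_idx = np.nonzero(upper)
    in_block = np.zeros(n, dtype=int)
    for k, block in enumerate(blocks, start=1):
        in_block[[idx[g] for g in block]] = k
    same_block = (in_block[a_idx] == in_block[b_idx]) & (in_block[a_idx] > 0)
    conf = np.where(
        same_block,
        rng.integers(700, 1001, size=len(a_idx)),
        rng.integers(400, 1001, size=len(a_idx)),
    )
    interactome_edges = pd.DataFrame(
        {
            "protein_a": [genes[i] for i in a_idx],
            "protein_b": [genes[i] for i in b_idx],
            "combined_score": conf.astype(int),
        }
    )

    # ontology: one branch per community, a disease branch and a
    # background branch, all under a single root
    edges = []
    branch_terms = {}
    def add_branch(name, n_terms):
        parent = f"P_{name}"
        edges.append((parent, "ROOT", "is_a"))
        terms = []
        for i in range(n_terms):
            t = f"{name}_{i + 1}"
            rel = "is_a" if i % 3 else "part_of"
            edges.append((t, parent, rel))
            terms.append(t)
        branch_terms[name] = terms
        return terms

    add_branch("DIS", 8)
    for m in range(cfg.n_communities):
        add_branch(f"M{m}", 6)
    add_branch("BG", 10)
    ontology_edges = pd.DataFrame(edges, columns=["child", "parent", "relation"])

    annotations = {}
    def annotate(gene_list, branch):
        terms = branch_terms[branch]
        for g in gene_list:
            k = int(rng.integers(1, 4))
            annotations[g] = sorted(
                rng.choice(terms, size=min(k, len(terms)), replace=False)
            )

    annotate(disease, "DIS")
    for m in range(cfg.n_communities):
        annotate(sorted(community_genes[f"M{m}"]), f"M{m}")
    annotate(background, "BG")

    return KnowledgeBase(
        drugs, drug_compounds, compound_targets, ob_table, interactome_edges,
        ontology_edges, annotations, set(disease), community_genes,
        effective_drugs, effective_compounds,
    )


def simulate_emr(cfg: SynthConfig, seed: int = 0) -> EMRData:
    """EMR-style prescription and symptom tables.

    Case patients co-receive the planted core drugs at the configured
    rate; the planted high-RR drugs appear much more often in cases than
    in other-hypertension controls; symptoms follow a stochastic block
    model over the planted communities.
    """
    rng = np.random.default_rng(seed)
    core = [f"H{i + 1:02d}" for i in range(cfg.n_core_drugs)]
    rr = [f"H{i + 1:02d}" for i in
          range(cfg.n_core_drugs, cfg.n_core_drugs + cfg.n_rr_drugs)]
    bg = [f"B{i + 1:02d}" for i in range(cfg.n_background_drugs)]
    drugs = core + rr + bg
    n_case, n_ctrl = cfg.n_patients, cfg.n_control_patients

    def draw(n, p_core, p_rr, p_bg):
        probs = np.array([p_core] * len(core) + [p_rr] * len(rr)
                         + [p_bg] * len(bg))
        return rng.random((n, len(drugs))) < probs

    mat_case = draw(n_case, cfg.core_coprescription_rate,
                    cfg.rr_drug_rate_case, cfg.background_drug_rate)
    mat_ctrl = draw(n_ctrl, cfg.core_rate_control,
                    cfg.rr_drug_rate_control, cfg.background_drug_rate)

    prescriptions = []
    for flag, mat, prefix in ((True, mat_case, "case"), (False, mat_ctrl, "ctrl")):
        for i in range(mat.shape[0]):
            chosen = [drugs[j] for j in np.nonzero(mat[i])[0]]
            if not chosen:  # keep records non-empty
                chosen = [drugs[int(rng.integers(len(drugs)))]]
            prescriptions.append(
                PrescriptionRecord(f"{prefix}{i + 1:04d}", frozenset(chosen), flag)
            )

    # symptoms: stochastic block model over planted communities
    n_sym = cfg.n_communities * cfg.n_symptoms_per_community
    symptoms_all = [f"S{i + 1:03d}" for i in range(n_sym)]
    blocks = {s: i // cfg.n_symptoms_per_community
              for i, s in enumerate(symptoms_all)}
    lo, hi = cfg.symptoms_per_patient
    symptom_records = []
    homes = rng.integers(cfg.n_communities, size=n_case)
    counts = rng.integers(lo, hi + 1, size=n_case)
    for i in range(n_case):
        home = int(homes[i])
        chosen = set()
        for _ in range(int(counts[i])):
            if rng.random() < cfg.symptom_home_affinity:
                j = home * cfg.n_symptoms_per_community + int(
                    rng.integers(cfg.n_symptoms_per_community))
            else:
                j = int(rng.integers(n_sym))
            chosen.add(symptoms_all[j])
        symptom_records.append(
            SymptomRecord(f"case{i + 1:04d}", frozenset(chosen))
        )

    return EMRData(prescriptions, symptom_records, core, rr, blocks)


def simulate_cohort(cfg: SynthConfig, seed: int = 0) -> pd.DataFrame:
    """Confounded two-arm retrospective cohort with a planted odds-scale
    treatment effect on CKD-stage improvement.

    Covariates are drawn near the real cohort's marginal scales (age ~
    N(62, 17), creatinine log-normal around 256 umol/L); the treated
    arm's covariate means are shifted toward healthier values, so the
    naive comparison is biased and IPTW is required to recover the
    planted effect.
    """
    rng = np.random.default_rng(seed)
    n_t, n_c = cfg.n_eligible_treated, cfg.n_eligible_control
    n = n_t + n_c
    treated = np.concatenate([np.ones(n_t, bool), np.zeros(n_c, bool)])
    shift = cfg.confounder_shift

    # arm-symmetric shifts (+-delta/2) keep the pooled marginals at the
    # study scales while planting the between-arm confounding
    arm = treated.astype(float) - 0.5
    age_sd, stay_sd, logscr_sd = 17.0, 7.3, 0.51
    age = rng.normal(62.0, age_sd, n) + arm * shift.get("age", 0) * age_sd
    age = np.clip(age, 18, 100)
    stay = rng.normal(16.7, stay_sd, n) + arm * shift.get("stay_days", 0) * stay_sd
    stay = np.clip(stay, 1, None)
    log_scr = rng.normal(5.41, logscr_sd, n) \
        + arm * shift.get("log_scr", 0) * logscr_sd
    scr = np.exp(log_scr)
    sex_male = rng.random(n) < 0.62
    bun = np.clip(rng.normal(13.5, 9.0, n), 1.5, None)
    urine_protein = rng.random(n) < 0.7

    eff = cfg.outcome_effects
    z = (
        np.log(cfg.control_improve_rate / (1 - cfg.control_improve_rate))
        + np.log(cfg.treatment_or) * treated
        + eff.get("age", 0) * (age - 62.0) / age_sd
        + eff.get("log_scr", 0) * (log_scr - 5.41) / logscr_sd
        + eff.get("stay_days", 0) * (stay - 16.7) / stay_sd
        + eff.get("sex_male", 0) * (sex_male.astype(float) - 0.62)
    )
    improved = rng.random(n) < 1.0 / (1.0 + np.exp(-z))

    return pd.DataFrame(
        {
            "patient_id": [f"pt{i + 1:04d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": np.where(sex_male, "male", "female"),
            "sex_male": sex_male.astype(int),
            "stay_days": np.round(stay, 1),
            "scr": np.round(scr, 1),
            "bun": np.round(bun, 2),
            "urine_protein": urine_protein.astype(int),
            "treated": treated.astype(int),
            "improved": improved.astype(int),
        }
    )
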
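"""Self-contained validation experiments over the synthetic community.

Each function builds its own inputs (the bundled survey table, or a
simulated community under the default study conditions), runs the
corresponding pipeline stage, and returns the measured quantities.  They
back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from . import ecology, function as func, pipeline, refsim, taxonomy, triage


# --- in-survey arithmetic -------------------------------------------------

def table1_consistency() -> dict:
    """Partition arithmetic of the bundled ten-sample survey table."""
    t = pipeline.load_survey_table1()
    parts = t.loc[["SSU", "LSU", "non_rRNA"]].sum(axis=0)
    conserved = int((parts == t.loc["total"]).sum())
    return {
        "samples_conserved": conserved,
        "n_samples": int(t.shape[1]),
        "total_reads": int(t.loc["total"].sum()),
        "non_rrna_reads": int(t.loc["non_rRNA"].sum()),
        "ssu_reads": int(t.loc["SSU"].sum()),
        "lsu_reads": int(t.loc["LSU"].sum()),
    }


def printed_ratios() -> dict:
    """Headline rates recomputed from the bundled survey counts."""
    t = pipeline.load_survey_table1()
    c = pipeline.load_survey_counts()
    return {
        "cog_assignment_rate_pct":
            100.0 * c["cog_assigned_reads"] / c["protein_homolog_reads"],
        "non_rrna_share_pct":
            100.0 * t.loc["non_rRNA"].sum() / t.loc["total"].sum(),
    }


# --- synthetic-recovery experiments --------------------------------------

def _default_world(seed: int):
    tree = refsim.build_taxonomy(5, 4)
    refs = refsim.evolve_references(tree, seed=seed)
    return tree, refs


def triage_recovery(seed: int = 1, n_samples: int = 10,
                    reads_per_sample: int = 20_000) -> dict:
    """Class recall/precision of the step-wise triage on a simulated
    community under the default study conditions."""
    tree, refs = _default_world(seed)
    spec = refsim.CommunitySpec(n_samples=n_samples,
                                reads_per_sample=reads_per_sample, seed=seed)
    reads = refsim.simulate_reads(spec, refs, tree)
    ssu_db = triage.rRNADatabase.from_records(refs.by_class("SSU"), tree)
    lsu_db = triage.rRNADatabase.from_records(refs.by_class("LSU"), tree)
    part = triage.triage_reads(reads, ssu_db, lsu_db)
    tp = {"SSU": 0, "LSU": 0}
    fp = {"SSU": 0, "LSU": 0}
    fn = {"SSU": 0, "LSU": 0}
    for sample in reads:
        for r in reads[sample]:
            if len(r) < 60:
                continue
            pred = {"SSU_prok": "SSU", "SSU_euk": "SSU"}.get(
                part.classes[r.id], part.classes[r.id])
            true = {"mRNA": "non_rRNA", "sRNA": "non_rRNA"}.get(
                r.true_class, r.true_class)
            for cls in ("SSU", "LSU"):
                if true == cls and pred == cls:
                    tp[cls] += 1
                elif true == cls:
                    fn[cls] += 1
                elif pred == cls:
                    fp[cls] += 1
    out = {"conservation_ok": part.check_conservation(),
           "n_reads": sum(len(v) for v in reads.values())}
    for cls in ("SSU", "LSU"):
        out[f"{cls.lower()}_recall"] = tp[cls] / (tp[cls] + fn[cls])
        out[f"{cls.lower()}_precision"] = tp[cls] / (tp[cls] + fp[cls])
    return out


def composition_recovery(seed: int = 1, n_samples: int = 10,
                         reads_per_sample: int = 5_000) -> dict:
    """L1 error between the naive-Bayes family composition (confidence
    threshold 0.5) and the truth-label composition of the same reads."""
    tree, refs = _default_world(seed)
    spec = refsim.CommunitySpec(
        n_samples=n_samples, reads_per_sample=reads_per_sample, seed=seed + 1,
        class_mixture={"SSU": 1.0, "LSU": 0.0, "mRNA": 0.0, "sRNA": 0.0})
    reads = refsim.simulate_reads(spec, refs, tree)
    model = taxonomy.train_word_model(refs)
    results, truth = [], {}
    for sample in reads:
        for r in reads[sample]:
            results.append(taxonomy.classify_nb(r, model, conf_threshold=0.5,
                                                seed=seed))
            fam = tree.ancestor_at_rank(r.true_node, "family")
            truth[fam] = truth.get(fam, 0) + 1
    total = sum(truth.values())
    truth = {k: v / total for k, v in truth.items()}
    comp = taxonomy.composition(results, tree)
    return {"l1_error": taxonomy.composition_l1(comp, truth),
            "n_reads": total,
            "unclassified_fraction":
                float(comp.counts.loc["uc_family"].sum()
                      / comp.counts.sum().sum())}


def calibration_experiment(seed: int = 1, n_per_class: int = 1000) -> dict:
    """Threshold sweep on the separable reference set, then with planted
    SSU carry-over in a diverged mRNA test set."""
    tree, refs = _default_world(seed)
    ssu_db = triage.rRNADatabase.from_records(refs.by_class("SSU"), tree)
    lsu_db = triage.rRNADatabase.from_records(refs.by_class("LSU"), tree)

    clean = triage.make_calibration_sets(refs, n_per_class=n_per_class, seed=seed)
    rep = triage.sweep_thresholds(clean, ssu_db, lsu_db)
    sel = rep.table.set_index(["database", "threshold"])
    out = {}
    for db in ("SSU", "LSU"):
        row = sel.loc[(db, rep.selected[db])]
        out[f"{db.lower()}_contamination"] = float(row["contamination"])
        out[f"{db.lower()}_sensitivity"] = float(row["sensitivity"])

    diverged = triage.make_calibration_sets(refs, n_per_class=n_per_class,
                                            seed=seed, divergence=0.2)
    planted = triage.plant_ssu_insertions(diverged, refs, fraction=0.1,
                                          insert_len=40, seed=seed)
    rep_p = triage.sweep_thresholds(planted, ssu_db, lsu_db)
    out["planted_selected_ssu"] = rep_p.selected["SSU"]
    out["planted_selected_lsu"] = rep_p.selected["LSU"]
    out["planted_ssu_stricter"] = rep_p.selected["SSU"] < rep_p.selected["LSU"]
    return out


def statistics_oracles(seed: int = 1) -> dict:
    """Closed-form estimators against exhaustive / independent oracles."""
    # rarefaction vs exhaustive enumeration on counts (4, 2)
    pool = [0] * 4 + [1] * 2
    rare_err = 0.0
    for n in range(1, 7):
        exact = float(np.mean([len(set(c))
                               for c in itertools.combinations(pool, n)]))
        rare_err = max(rare_err, abs(ecology.rarefaction([4, 2], [n])[0] - exact))
    # Chao1 / ACE / Shannon hand-evaluated fixtures
    chao_err = abs(ecology.chao1([1, 1, 2, 2, 3])[0] - 6.0)
    c_ace = 1 - 1 / 6
    gamma2 = max(3 * 8 / (c_ace * 6 * 5) - 1, 0.0)
    ace_expect = 1 + 3 / c_ace + 1 * gamma2 / c_ace
    ace_err = abs(ecology.ace([1, 2, 3, 15], se_bootstrap=0)[0] - ace_expect)
    sh_expect = -(0.5 * np.log(0.5) + 0.3 * np.log(0.3) + 0.2 * np.log(0.2))
    sh_err = abs(ecology.shannon([5, 3, 2]) - sh_expect)
    # CA inertia vs Pearson chi-square / N on random 5x8 tables
    rng = np.random.default_rng(seed)
    ca_err = 0.0
    for _ in range(5):
        t = pd.DataFrame(rng.integers(1, 60, size=(5, 8)))
        res = ecology.correspondence_analysis(t)
        chi2 = stats.chi2_contingency(t.to_numpy(), correction=False)[0]
        ca_err = max(ca_err, abs(res.total_inertia - chi2 / t.to_numpy().sum()))
    return {"rarefaction_max_abs_err": rare_err,
            "chao1_abs_err": chao_err,
            "ace_abs_err": ace_err,
            "shannon_abs_err": sh_err,
            "ca_inertia_max_abs_err": ca_err}


def enrichment_recovery(seed: int = 1, n_samples: int = 10,
                        reads_per_sample: int = 600) -> dict:
    """Rate-ratio recovery of the injected COG category skew (category G
    expressed at twice its database share) on pooled assignments."""
    tree, refs = _default_world(seed)
    spec = refsim.CommunitySpec(
        n_samples=n_samples, reads_per_sample=reads_per_sample, seed=seed + 2,
        class_mixture={"SSU": 0.0, "LSU": 0.0, "mRNA": 1.0, "sRNA": 0.0})
    reads = refsim.simulate_reads(spec, refs, tree)
    flat = [r for v in reads.values() for r in v if len(r) >= 60]
    pdb = func.ProteinDatabase.from_records(refs)
    hits, _ = func.call_protein_coding(flat, pdb)
    assignments = func.assign_cog([r for r in flat if r.id in hits], pdb,
                                  hits=hits)
    rr = func.rate_ratios(assignments, pdb)
    self_ratios = func.database_self_ratios(pdb).dropna()
    return {"ratio_g": rr.ratio("G"),
            "ratio_i": rr.ratio("I"),
            "n_assignments": int(sum(not a.discarded for a in assignments)),
            "selfdb_max_abs_dev": float((self_ratios - 1.0).abs().max())}
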
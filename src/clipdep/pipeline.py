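"""End-to-end synthetic pipeline run with recovery metrics against truth.

Each stage consumes only what the corresponding real-data stage would see
(peak tables, count tables, abundance tables); the planted truth labels are
used solely to score recovery afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import clip, motifs, rescue, rip, rnadep, synth
from .intervals import filter_by_score

__all__ = ["DemoReport", "run_demo"]

LET7A = "UGAGGUAGUAGGUUGUAUAGUU"


@dataclass
class DemoReport:
    metrics: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        width = max(len(k) for k in self.metrics)
        lines = ["End-to-end synthetic recovery report", "=" * (width + 14)]
        for k, v in self.metrics.items():
            lines.append(f"{k:<{width}}  {v:>10.4g}")
        return "\n".join(lines)


def _sens_spec(pred: set[str], truth_pos: set[str], universe: set[str]):
    tp = len(pred & truth_pos)
    fn = len(truth_pos - pred)
    neg = universe - truth_pos
    tn = len(neg - pred)
    fp = len(pred & neg)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    fp_rate_of_calls = fp / len(pred) if pred else 0.0
    return sens, spec, fp_rate_of_calls


def run_demo(
    seed: int = 0,
    cfg: synth.SynthConfig | None = None,
    n_shuffles: int = 1000,
) -> DemoReport:
    """Simulate every input table, run every stage, score recovery."""
    cfg = cfg or synth.SynthConfig(seed=seed)
    m: dict[str, float] = {}

    # --- proteomics: RNA-dependency classification -----------------------
    records, ipms_truth = synth.make_ipms_table(cfg)
    kept = rnadep.filter_candidates(records)
    res = rnadep.RnaDependencyModel(kept, bait_id=cfg.ipms.bait_id).fit()
    dep_called = set(
        res.table.loc[res.table["rna_class"] == "dependent", "protein_id"]
    )
    dep_true = set(ipms_truth.loc[ipms_truth["dependent"], "protein_id"])
    universe = set(res.table["protein_id"])
    sens, spec, _ = _sens_spec(dep_called, dep_true & universe, universe)
    m["rnadep_n_classified"] = len(universe)
    m["rnadep_n_dependent"] = res.n_dependent
    m["rnadep_n_independent"] = res.n_independent
    m["rnadep_sensitivity"] = sens
    m["rnadep_specificity"] = spec

    # --- CLIP: dependency merge, distance categories, shuffle test -------
    txome = synth.make_transcriptome(cfg)
    peaks = synth.make_peaks(cfg, txome)
    ago2 = filter_by_score(peaks.ago2_all, 7.0)
    merged = clip.dependent_peak_merge(
        ago2, peaks.ago2_filter1, peaks.ago2_filter2
    )
    calls = clip.categorize_by_distance(
        ago2, peaks.sfpq, txome.annotation,
        reduced_names={iv.name for iv in merged},
    )
    direct_called = {
        c.ago2_peak.name
        for c in calls
        if c.reduced_on_knockdown and c.distance_category.value == "close"
    }
    direct_true = set(
        peaks.truth.loc[peaks.truth["planted"] == "direct", "name"]
    )
    uni = {iv.name for iv in ago2}
    sens, _spec, fpr = _sens_spec(direct_called, direct_true, uni)
    m["direct_recovery"] = sens
    m["direct_false_positive_rate"] = fpr
    fisher = clip.category_enrichment_test(calls, region="UTR3")
    m["fisher_p_close_vs_far"] = fisher["p_close_vs_far"]
    m["fisher_p_close_vs_very_far"] = fisher["p_close_vs_very_far"]

    reduced = ago2.subset(direct_true & uni, label="reduced")
    shuffle = clip.ShuffleTest(
        reduced, peaks.sfpq, txome.annotation,
        n_shuffles=n_shuffles, seed=seed,
    ).fit()
    for b in shuffle.bins:
        m[f"shuffle_z_{b.bin_lo}_{b.bin_hi}"] = b.z

    indep_calls = [c for c in calls if c.ago2_peak.name not in direct_true]
    m["pct_independent_close_utr3"] = clip.fraction_independent_close(
        indep_calls, region="UTR3"
    )

    # --- motifs: Sfpq peak sequences vs windows from unoccupied 3'UTRs ---
    meta_by_tx = txome.meta.set_index("transcript_id")
    sfpq_hosts = clip.find_host_utrs(peaks.sfpq, txome.annotation)
    fg = []
    for iv in peaks.sfpq:
        tx, _utr = sfpq_hosts[iv.name]
        rel = iv.start - int(meta_by_tx.loc[tx, "utr_start"])
        fg.append(txome.sequences[tx][rel : rel + iv.length])
    unocc = sorted(set(txome.sequences) - set(
        txome.meta.loc[txome.meta["occupied"], "transcript_id"]
    ))
    rng = np.random.default_rng(seed + 21)
    bg = []
    for s in fg:
        tx = unocc[int(rng.integers(0, len(unocc)))]
        seq = txome.sequences[tx]
        if len(seq) <= len(s):
            continue
        pos = int(rng.integers(0, len(seq) - len(s)))
        bg.append(seq[pos : pos + len(s)])
    p_motif, _odds = motifs.motif_enrichment_test(fg, bg, [motifs.MOTIF1, motifs.MOTIF2])
    m["motif_enrichment_p"] = p_motif
    rho, r = motifs.occurrence_length_correlation(fg, [motifs.MOTIF1, motifs.MOTIF2])
    m["motif_count_length_spearman"] = rho
    m["motif_count_length_pearson"] = r

    # --- RIP: mixture enrichment calling ---------------------------------
    bundle = synth.make_rip_counts(cfg, nested=True)
    res_a = rip.RipEnrichmentModel(bundle.records, seed=seed).fit()
    truth_enr = set(
        bundle.truth.loc[bundle.truth["enriched"], "mirna_id"]
    )
    uni_r = {c.mirna_id for c in res_a.calls}
    sens, spec, _ = _sens_spec(res_a.enriched_ids, truth_enr & uni_r, uni_r)
    m["rip_n_tested"] = len(uni_r)
    m["rip_n_enriched"] = len(res_a.enriched_ids)
    m["rip_sensitivity"] = sens
    m["rip_specificity"] = spec
    m["rip_mixture_mu0"] = res_a.mixture.means[0]
    m["rip_mixture_mu1"] = res_a.mixture.means[1]
    res_b = rip.RipEnrichmentModel(bundle.records_nested, seed=seed).fit()
    inter = res_a.enriched_ids & res_b.enriched_ids
    m["rip_nested_overlap_frac"] = (
        len(inter) / len(res_b.enriched_ids) if res_b.enriched_ids else float("nan")
    )

    # --- expression rescue -----------------------------------------------
    groups = synth.derive_transcript_groups(peaks.truth)
    expr = synth.make_expression(cfg, groups)
    tx_of = dict(zip(peaks.truth["name"], peaks.truth["transcript_id"]))
    seed_sites = {}
    for name in direct_true:
        tx = tx_of[name]
        sites = motifs.seed_scan(txome.sequences[tx], LET7A, "let-7a")
        if sites:
            # keep only sites inside this peak's span on the UTR
            row = txome.meta[txome.meta["transcript_id"] == tx].iloc[0]
            iv = next(p for p in ago2 if p.name == name)
            lo, hi = iv.start - row.utr_start, iv.end - row.utr_start
            inside = [s for s in sites if lo <= s.position < hi]
            if inside:
                seed_sites[name] = inside
    recs = rescue.assign_groups(
        expr, calls, tx_of, seed_sites_by_peak=seed_sites
    )
    for grp in ("canonical_direct", "independent"):
        try:
            t = rescue.rescue_test(recs, grp)
            m[f"rescue_p_{grp}"] = t["p_paired"]
            m[f"rescue_median_delta_{grp}"] = t["median_delta"]
        except ValueError:
            m[f"rescue_p_{grp}"] = float("nan")

    # --- 3'UTR length structure ------------------------------------------
    meta = txome.meta
    lengths_all = (meta["utr_end"] - meta["utr_start"]).to_numpy()
    occ_mask = meta["occupied"].to_numpy()
    dep_tx = set(
        peaks.truth.loc[peaks.truth["planted"] == "direct", "transcript_id"]
    )
    dep_mask = meta["transcript_id"].isin(dep_tx).to_numpy()
    utr_p = clip.utr_length_comparison(
        lengths_all, lengths_all[occ_mask], lengths_all[dep_mask]
    )
    m["utr_len_p_occupied_vs_all"] = utr_p["p_occupied_vs_all"]
    return DemoReport(m)
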
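"""End-to-end demo orchestration on synthetic fixtures.

``run_demo`` generates one fixture of every input class, runs each analysis
stage (enrichment -> reporter -> calcium -> behavior), writes the fixture
files, per-stage result tables, two summary figures, and one
machine-readable ``results.json``. The whole run is a pure function of
(config, seed): the results JSON is byte-identical across repeat runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, calcium, enrichment, io, reporter_quant
from . import synthetic_data as syn
from .config import PipelineConfig

log = logging.getLogger("awapipe")


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds from one master seed (splittable scheme)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _stage(name):
    log.info("stage: %s", name)


def run_demo(config: PipelineConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s_expr, s_atlas, s_img, s_ca, s_beh = _sub_seeds(config.seed, 5)
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.hash,
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    try:
        # -- enrichment ------------------------------------------------------
        _stage("enrichment")
        table, truth = syn.gen_expression_table(
            n_genes=2000, n_up_chemo=20, n_up_other=30,
            fold_range=(5.0, 8.0), noise_cv=0.05, n_replicates=3, seed=s_expr)
        io.write_expression_tsv(table, out / "expression.tsv")
        io.write_truth_json(truth, out / "expression_truth.json")
        fc = enrichment.compute_fold_changes(table, pseudocount=config.de_pseudocount)
        sets = enrichment.select_regulated(fc, threshold=config.de_threshold)
        odds, p_global, tab = enrichment.family_enrichment_test(
            sets, syn.CHEMO_FAMILY, table)
        up_chemo = {g for g in sets.upregulated if g.startswith("chemo")}
        all_chemo = sorted(fc.loc[fc["family"] == syn.CHEMO_FAMILY, "gene_id"])
        atlas = syn.gen_neuron_atlas(
            n_neurons=12, genes=all_chemo, expressed_prob=0.25,
            planted_neuron="AWA", planted_excess=3.0,
            target_genes=up_chemo, seed=s_atlas)
        io.write_atlas_tsv(atlas, out / "atlas.tsv")
        per_neuron = enrichment.neuron_enrichment(
            up_chemo, all_chemo, atlas, alpha=config.atlas_alpha)
        per_neuron.to_csv(out / "neuron_enrichment.tsv", sep="\t", index=False)
        pd.Series(sorted(sets.upregulated)).to_csv(
            out / "upregulated_genes.txt", index=False, header=False)
        report["stages"]["enrichment"] = {
            "n_up": len(sets.upregulated),
            "n_down": len(sets.downregulated),
            "family_odds_ratio": odds,
            "family_fisher_p": p_global,
            "significant_neurons": sorted(
                per_neuron.loc[per_neuron["significant"], "neuron"]),
        }

        # -- reporter --------------------------------------------------------
        _stage("reporter_quant")
        rows = []
        img_seeds = _sub_seeds(s_img, 24)
        i = 0
        for session in ("day1", "day2"):
            for group, amp in (("fed_WT", 40.0), ("fasted", 200.0)):
                for _ in range(6):
                    stack, _a = syn.gen_image_stack(
                        shape=(12, 48, 48), background_level=100.0,
                        soma_amplitude=amp, soma_sigma=2.5, noise_sd=4.0,
                        seed=img_seeds[i])
                    raw = reporter_quant.score_stack(
                        stack, box_halfwidth=config.roi_halfwidth)
                    rows.append({"sample": f"worm-{i:02d}", "session": session,
                                 "group": group, "raw": raw})
                    i += 1
        scores = reporter_quant.normalize_by_control(
            pd.DataFrame(rows), config.control_group)
        scores.to_csv(out / "reporter_scores.csv", index=False)
        cmp_df = reporter_quant.compare_conditions(
            scores, [("fasted", "fed_WT")])
        report["stages"]["reporter"] = {
            "fasted_over_fed_mean": float(
                scores.loc[scores["group"] == "fasted", "normalized"].mean()),
            "t_p_adj": float(cmp_df["p_adj"].iloc[0]),
        }

        # -- calcium ---------------------------------------------------------
        _stage("calcium")
        ca_seeds = _sub_seeds(s_ca, 12)
        binned_rows = []
        peak_amps = {"fed": [], "fasted": []}
        for j, state in enumerate(["fed"] * 6 + ["fasted"] * 6):
            amp_scale = 1.0 if state == "fed" else 2.0
            rng = np.random.default_rng(ca_seeds[j])
            onsets = np.arange(8.0, 110.0, 9.0) + rng.uniform(0, 2, 12)
            transients = [
                syn.TransientTruth(float(t), float(rng.uniform(0.5, 1.0) * amp_scale))
                for t in onsets
            ]
            rec, _tr = syn.gen_gcamp_recording(
                duration=120.0, transients=transients, noise_sd=1.5,
                seed=ca_seeds[j])
            trace = calcium.compute_dff(rec, window=config.median_window,
                                        q=config.baseline_percentile)
            peaks = calcium.detect_peaks(
                trace, min_amplitude=config.peak_min_amplitude,
                min_separation=config.peak_min_separation_s)
            peak_amps[state].extend(p.amplitude for p in peaks)
            dist = calcium.distance_to_lawn(rec.position, rec.lawn)
            binned = calcium.bin_dff_by_distance(trace.dff, dist,
                                                 bin_width=config.bin_width_mm)
            for r in binned.itertuples():
                if r.n > 0 and -1.0 <= r.bin_left <= 2.0:
                    binned_rows.append({"animal": f"a{j}", "state": state,
                                        "bin": r.bin_left, "value": r.mean})
            if j == 0:
                io.write_recording_csv(rec, out / "recording_example.csv",
                                       lawn_path=out / "lawn.json")
        binned_df = pd.DataFrame(binned_rows)
        binned_df.to_csv(out / "binned_dff.csv", index=False)
        anova = calcium.state_effect_anova(binned_df)
        report["stages"]["calcium"] = {
            "mean_peak_amp_fed": float(np.mean(peak_amps["fed"])),
            "mean_peak_amp_fasted": float(np.mean(peak_amps["fasted"])),
            "anova_state_p": anova["state"][1],
        }

        # -- behavior --------------------------------------------------------
        _stage("behavior")
        b1, b2, b3 = _sub_seeds(s_beh, 3)
        ct = syn.gen_assay_counts("chemotaxis", true_index=0.6, n_animals=120,
                                  n_plates=10, other_prob=0.1, seed=b1)
        fc_counts = syn.gen_assay_counts("food_choice", true_index=0.75,
                                         n_animals=120, n_plates=10,
                                         other_prob=0.1, seed=b2)
        io.write_counts_csv(ct, out / "chemotaxis_counts.csv")
        io.write_counts_csv(fc_counts, out / "food_choice_counts.csv")
        ci = behavior.plate_indices(ct, "chemotaxis")
        fci = behavior.plate_indices(fc_counts, "food_choice")
        rng = np.random.default_rng(b3)
        steps = rng.normal(0, 0.8, size=(600, 2))
        track = 30.0 + np.cumsum(steps, axis=0)
        track = np.clip(track, 1.0, 59.0)
        coverage = behavior.exploration_coverage(
            track, square_mm=config.grid_square_mm,
            plate_diameter=config.plate_diameter_mm)
        speed, mean_speed = behavior.centroid_speed(
            np.arange(track.shape[0]) / 3.0, track)
        report["stages"]["behavior"] = {
            "chemotaxis_index_mean": ci.attrs["mean"],
            "chemotaxis_index_sem": ci.attrs["sem"],
            "food_choice_index_mean": fci.attrs["mean"],
            "food_choice_index_sem": fci.attrs["sem"],
            "exploration_squares": coverage,
            "mean_speed_mm_s": mean_speed,
        }

        _write_figures(fc, sets, binned_df, out)
    except Exception as err:  # annotate the failing stage, keep prior outputs
        done = list(report["stages"])
        raise RuntimeError(
            f"demo failed after stages {done}: {err}") from err

    with open(out / "results.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _write_figures(fc, sets, binned_df, out: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    is_chemo = fc["family"] == syn.CHEMO_FAMILY
    ax.scatter(np.arange(len(fc))[~is_chemo], np.log2(fc["ratio"][~is_chemo]),
               s=4, c="0.6", label="other")
    ax.scatter(np.arange(len(fc))[is_chemo], np.log2(fc["ratio"][is_chemo]),
               s=6, c="seagreen", label="chemoreceptor")
    ax.axhline(np.log2(sets.threshold), ls="--", c="green")
    ax.axhline(-np.log2(sets.threshold), ls="--", c="red")
    ax.set_xlabel("gene")
    ax.set_ylabel("log2 fasted/fed ratio")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "fold_changes.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for state, sub in binned_df.groupby("state"):
        prof = sub.groupby("bin")["value"].mean()
        ax.plot(prof.index, prof.values, marker="o", label=state)
    ax.set_xlabel("distance to lawn boundary (mm)")
    ax.set_ylabel("mean dF/F0")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "binned_dff.png", dpi=120)
    plt.close(fig)
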
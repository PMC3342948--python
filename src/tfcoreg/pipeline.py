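"""End-to-end orchestration on synthetic data.

Runs the full analysis shape with one config and one master seed:
simulate -> call peaks -> RSA-rank both knockdowns -> co-regulation curve
and top-k overlap tests -> motif enrichment -> site specificity and
peak-to-gene assignment.  Per-stage sub-seeds are derived from the master
seed by a fixed counter scheme (seed * 10 + stage index, kept below 2**31),
so any stage can be re-run independently yet reproducibly.  A manifest
records parameters and sha256 digests of every stage output; re-running
with the same config and seed reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import coreg, interval_ops, io, motif, rsa, simulate, skellam

STAGES = ("simulate", "callpeaks", "rsa", "coreg", "motif", "overlap")

DEFAULT_CONFIG: dict = {
    "chip": {"n_peaks": 50, "peak_width": 300, "enrichment": 8.0,
             "chip_depth": 400_000, "ctrl_depth": 250_000},
    "peaks": {"window_size": 200, "step": 50, "p_cutoff": 1e-6},
    "expression": {"n_genes": 2000, "effect": 1.5, "noise_sd": 0.3,
                   "class_sizes": dict(simulate.DEFAULT_CLASS_SIZES)},
    "rsa": {"q_cutoff": 0.01, "lambda": 0.5},
    "coreg": {"n_boot": 100, "n_perm": 1000, "span": 0.3, "grid_size": 50,
              "k_grid": [100, 200, 300, 400]},
    "motif": {"consensus": "CATGTGAC", "n_fg": 300, "n_bg": 300,
              "region_length": 200, "plant_rate_fg": 0.4,
              "plant_rate_bg": 0.05, "n_perm_calibration": 200},
    "overlap": {"n_a": 100, "n_b": 100, "overlap_target": 0.3,
                "specificity_distance": 5000},
}


def _substage_seed(master: int, stage: str) -> int:
    return (master * 10 + STAGES.index(stage)) % (2**31 - 1)


def _merge(base: dict, override: dict | None) -> dict:
    out = json.loads(json.dumps(base))
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: dict | None) -> dict:
    cfg = _merge(DEFAULT_CONFIG, config)
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    for section, defaults in DEFAULT_CONFIG.items():
        bad = set(cfg[section]) - set(defaults)
        if bad:
            raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
    return cfg


def run_all(config: dict | None = None, seed: int = 42,
            outdir: str | Path = "tfcoreg_run") -> dict:
    """Execute every stage in dependency order; returns the run manifest."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    manifest: dict = {"config": cfg, "seed": seed, "stages": {}, "results": {}}

    # --- stage 1: simulate --------------------------------------------------
    sdir = outdir / "simulate"
    sdir.mkdir(parents=True, exist_ok=True)
    s_seed = _substage_seed(seed, "simulate")
    chip_spec = simulate.ChipSimSpec(seed=s_seed, **cfg["chip"])
    chip, ctrl, truth_peaks = simulate.simulate_chipseq(chip_spec)
    expr_spec = simulate.ExprSimSpec(seed=s_seed + 1, **cfg["expression"])
    t_mitf, t_yy1, labels = simulate.simulate_expression(expr_spec)
    pwm = motif.PositionWeightMatrix.from_consensus(
        cfg["motif"]["consensus"], motif_id="planted")
    motif_spec = simulate.MotifSimSpec(
        n_fg=cfg["motif"]["n_fg"], n_bg=cfg["motif"]["n_bg"],
        region_length=cfg["motif"]["region_length"], pwm=pwm,
        plant_rate_fg=cfg["motif"]["plant_rate_fg"],
        plant_rate_bg=cfg["motif"]["plant_rate_bg"], seed=s_seed + 2)
    fg, bg, motif_truth = simulate.simulate_sequences(motif_spec)
    set_a, set_b = simulate.simulate_peak_sets(
        cfg["overlap"]["n_a"], cfg["overlap"]["n_b"],
        cfg["overlap"]["overlap_target"], seed=s_seed + 3)

    io.write_bed(truth_peaks, sdir / "truth_peaks.bed")
    io.write_foldchange_table(t_mitf, sdir / "fc_mitf.tsv")
    io.write_foldchange_table(t_yy1, sdir / "fc_yy1.tsv")
    io.write_fasta(fg, sdir / "fg.fasta")
    io.write_fasta(bg, sdir / "bg.fasta")
    io.write_bed(set_a, sdir / "set_a.bed")
    io.write_bed(set_b, sdir / "set_b.bed")
    io.write_json_summary({"labels": labels, "motif_truth": motif_truth},
                          sdir / "truth.json")
    manifest["stages"]["simulate"] = {"seed": s_seed}

    # --- stage 2: peak calling ---------------------------------------------
    pdir = outdir / "callpeaks"
    pdir.mkdir(exist_ok=True)
    peaks, peak_summary = skellam.call_peaks(
        chip, ctrl, window_size=cfg["peaks"]["window_size"],
        step=cfg["peaks"]["step"], p_cutoff=cfg["peaks"]["p_cutoff"])
    io.write_bed([p.interval for p in peaks], pdir / "peaks.bed")
    n_recovered = sum(
        any(p.interval.overlaps(t) for p in peaks) for t in truth_peaks)
    fp = sum(not any(p.interval.overlaps(t) for t in truth_peaks) for p in peaks)
    peak_summary["recall"] = n_recovered / max(len(truth_peaks), 1)
    peak_summary["false_positives"] = fp
    io.write_json_summary(peak_summary, pdir / "summary.json")
    manifest["results"]["callpeaks"] = {
        "n_peaks": len(peaks), "recall": peak_summary["recall"],
        "false_positives": fp}

    # --- stage 3: RSA ranking ----------------------------------------------
    rdir = outdir / "rsa"
    rdir.mkdir(exist_ok=True)
    rec_mitf = rsa.score_genes(t_mitf, lambda_=cfg["rsa"]["lambda"])
    rec_yy1 = rsa.score_genes(t_yy1, lambda_=cfg["rsa"]["lambda"])
    rsa.records_to_frame(rec_mitf).to_csv(rdir / "rsa_mitf.tsv", sep="\t", index=False)
    rsa.records_to_frame(rec_yy1).to_csv(rdir / "rsa_yy1.tsv", sep="\t", index=False)
    q = cfg["rsa"]["q_cutoff"]
    sig = {
        "mitf_down": len(rsa.significant_genes(rec_mitf, q, "down")),
        "mitf_up": len(rsa.significant_genes(rec_mitf, q, "up")),
        "yy1_down": len(rsa.significant_genes(rec_yy1, q, "down")),
        "yy1_up": len(rsa.significant_genes(rec_yy1, q, "up")),
    }
    down_truth = {g for g, c in labels.items() if c in ("co_activated", "mitf_only")}
    found = rsa.significant_genes(rec_mitf, q, "down")
    tp = len(found & down_truth)
    manifest["results"]["rsa"] = {
        **sig,
        "precision_mitf_down": tp / max(len(found), 1),
        "recall_mitf_down": tp / max(len(down_truth), 1),
    }
    io.write_json_summary(manifest["results"]["rsa"], rdir / "summary.json")

    # --- stage 4: co-regulation --------------------------------------------
    cdir = outdir / "coreg"
    cdir.mkdir(exist_ok=True)
    c_seed = _substage_seed(seed, "coreg")
    x = t_mitf.values.mean(axis=1)
    y = t_yy1.values.mean(axis=1)
    curve = coreg.coreg_curve(x, y, n_boot=cfg["coreg"]["n_boot"],
                              n_perm=cfg["coreg"]["n_perm"],
                              span=cfg["coreg"]["span"],
                              grid_size=cfg["coreg"]["grid_size"], seed=c_seed)
    np.savetxt(cdir / "curve.tsv",
               np.column_stack([curve.grid, curve.bagged, curve.env_lo, curve.env_hi]),
               delimiter="\t", header="grid\tbagged\tenv_lo\tenv_hi", comments="")
    p_down_m = {r.gene_id: r.p_down for r in rec_mitf}
    p_up_m = {r.gene_id: r.p_up for r in rec_mitf}
    p_down_y = {r.gene_id: r.p_down for r in rec_yy1}
    p_up_y = {r.gene_id: r.p_up for r in rec_yy1}
    points = coreg.overlap_significance_curve(
        p_down_m, p_down_y, cfg["coreg"]["k_grid"],
        rank_a_up=p_up_m, rank_b_up=p_up_y)
    with open(cdir / "overlap_curve.tsv", "w") as fh:
        fh.write("k\tmode\toverlap\tfisher_p\n")
        for pt in points:
            fh.write(f"{pt.k}\t{pt.mode}\t{pt.overlap}\t{pt.fisher_p:.6g}\n")
    verdict = {}
    for mode in coreg.MODES:
        ps = [pt.fisher_p for pt in points if pt.mode == mode]
        verdict[mode] = {"max_p": max(ps), "min_p": min(ps),
                         "significant": max(ps) < 1e-6}
    manifest["results"]["coreg"] = {
        "modes": verdict,
        "n_grid_points_outside_envelope": int(curve.exits_envelope().sum()),
        "n_grid_points": int(curve.grid.size),
    }
    io.write_json_summary(manifest["results"]["coreg"], cdir / "summary.json")

    # --- stage 5: motif enrichment -----------------------------------------
    mdir = outdir / "motif"
    mdir.mkdir(exist_ok=True)
    m_seed = _substage_seed(seed, "motif")
    fg_scores = motif.score_regions(pwm, fg)
    bg_scores = motif.score_regions(pwm, bg)
    enr = motif.optimal_cutoff_binomial(fg_scores, bg_scores, pwm.motif_id)
    enr.p_calibrated = motif.calibrate_by_label_permutation(
        fg_scores, bg_scores, n_perm=cfg["motif"]["n_perm_calibration"],
        seed=m_seed)
    manifest["results"]["motif"] = {
        "motif_id": enr.motif_id, "direction": enr.direction,
        "cutoff": enr.cutoff, "p_binomial": enr.p_binomial,
        "p_calibrated": enr.p_calibrated,
        "fg_hits": enr.fg_hits, "fg_total": enr.fg_total,
        "bg_hits": enr.bg_hits, "bg_total": enr.bg_total,
    }
    io.write_json_summary(manifest["results"]["motif"], mdir / "summary.json")

    # --- stage 6: interval analyses ----------------------------------------
    odir = outdir / "overlap"
    odir.mkdir(exist_ok=True)
    rep = interval_ops.overlap_fraction(set_a, set_b, set_a_id="A", set_b_id="B")
    called = [p.interval for p in peaks]
    specificity = None
    if called:
        kept = interval_ops.specific_sites(
            called, [set_a], distance=cfg["overlap"]["specificity_distance"])
        specificity = {"n_input": len(called), "n_specific": len(kept)}
    manifest["results"]["overlap"] = {
        "fraction_a_in_b": rep.fraction, "n_a": rep.n_a, "n_b": rep.n_b,
        "specificity": specificity,
    }
    io.write_json_summary(manifest["results"]["overlap"], odir / "summary.json")

    # --- manifest -----------------------------------------------------------
    for stage in STAGES:
        d = outdir / stage
        if d.is_dir():
            manifest["stages"].setdefault(stage, {})
            manifest["stages"][stage]["digests"] = {
                f.name: _digest(f) for f in sorted(d.iterdir()) if f.is_file()}
            manifest["stages"][stage]["seed"] = _substage_seed(seed, stage)
    io.write_json_summary(manifest, outdir / "manifest.json")
    return manifest


def report(manifest: dict) -> str:
    """One-page human-readable summary of a completed run."""
    res = manifest.get("results")
    if not res or not manifest.get("stages"):
        raise ValueError("incomplete manifest: run_all must have finished")
    lines = [f"tfcoreg run (seed {manifest['seed']})", "=" * 40]
    pk = res["callpeaks"]
    lines.append(f"peaks: {pk['n_peaks']} called")
    if "recall" in pk:
        lines.append(f"  recovery vs truth: recall {pk['recall']:.3f}, "
                     f"{pk['false_positives']} false positives")
    rs = res["rsa"]
    lines.append("differential expression (RSA):")
    lines.append(f"  MITF-side: {rs['mitf_down']} down / {rs['mitf_up']} up; "
                 f"YY1-side: {rs['yy1_down']} down / {rs['yy1_up']} up")
    if "precision_mitf_down" in rs:
        lines.append(f"  planted-down recovery: precision "
                     f"{rs['precision_mitf_down']:.3f}, "
                     f"recall {rs['recall_mitf_down']:.3f}")
    cg = res["coreg"]
    lines.append("co-regulation overlap modes:")
    for mode, v in cg["modes"].items():
        tag = "significant" if v["significant"] else "not significant"
        lines.append(f"  {mode}: max p {v['max_p']:.3g} -> {tag}")
    lines.append(f"  lowess curve outside null envelope at "
                 f"{cg['n_grid_points_outside_envelope']}/{cg['n_grid_points']} "
                 "grid points")
    mt = res["motif"]
    lines.append(f"motif {mt['motif_id']}: {mt['direction']}-represented, "
                 f"cutoff {mt['cutoff']:.2f}, binomial p {mt['p_binomial']:.3g}, "
                 f"calibrated p {mt['p_calibrated']:.3g} "
                 f"({mt['fg_hits']}/{mt['fg_total']} fg vs "
                 f"{mt['bg_hits']}/{mt['bg_total']} bg)")
    ov = res["overlap"]
    lines.append(f"peak-set overlap: {ov['fraction_a_in_b']:.2f} of A in B "
                 f"(n_a={ov['n_a']}, n_b={ov['n_b']})")
    if ov.get("specificity"):
        sp = ov["specificity"]
        lines.append(f"  specificity filter kept {sp['n_specific']}/{sp['n_input']} "
                     "called peaks")
    return "\n".join(lines)
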
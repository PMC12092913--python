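"""End-to-end orchestration: simulate -> filter -> scan -> merge/subtract ->
trajectories -> overlap -> Ne summaries, with a manifest and report.

Each stage writes plain-text outputs (TSV/BED/JSON/sync) into the run
directory; the manifest records the config snapshot, seeds, and a checksum
for every output file so a rerun with the same manifest is verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import popgen, trajectories as traj_mod
from .overlap_perm import (IntervalSet, fisher_exact_overlap,
                           permutation_overlap_test, replicate_sharing_histogram)
from .selection_scan import (ScanResult, call_and_merge_loci, cmh_sites,
                             pfst_sites, subtract_impaired, window_fisher)
from .synthetic_cage import (CONTROL_COLOR, DesignConfig, SelectionRegime,
                             build_design, sample_sequencing, simulate_experiment)
from .variants_io import filter_sites

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 42,
    "design": {},
    "regime": {"s": 0.1, "n_trait_loci": 10, "ne": 200, "direction": "darker"},
    "simulation": {"n_sites": 2000, "founder_skew": "neutral"},
    "scan": {
        # top_fraction is a genome-scale knob: 0.1% of 4.57M real sites is
        # thousands of sites, so desk-scale runs with ~10^3 simulated sites
        # use 1% to keep the dual-threshold outlier rule meaningful
        "epsilon": 0.01, "maf_min": 0.10, "cov_min": 10.0,
        "top_fraction": 0.01, "q_alpha": 0.05, "merge_distance": 500,
        "window_size": 10_000, "step": 50_000, "outlier_rule": "intersection",
    },
    "overlap": {"n_permutations": 2000},
    "make_plots": False,
}


def load_config(source) -> dict:
    """Merge a YAML path / dict over the defaults (one level deep)."""
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = {}
    for key, default in DEFAULT_CONFIG.items():
        if isinstance(default, dict):
            cfg[key] = {**default, **user.get(key, {})}
        else:
            cfg[key] = user.get(key, default)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config=None, out_dir="runs/run1") -> dict:
    """Execute the full analysis on a simulated experiment; returns the
    run manifest (also written to ``manifest.json``)."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(cfg["seed"])
    sim_seed, seq_seed, perm_seed = (int(s) for s in root.integers(2**31 - 1, size=3))

    # -- stage 1: simulate and sequence -----------------------------------
    design_cfg = DesignConfig(**cfg["design"])
    regime = SelectionRegime(**cfg["regime"])
    sim = simulate_experiment(
        design_cfg, regime, seed=sim_seed,
        n_sites=cfg["simulation"]["n_sites"],
        founder_skew=cfg["simulation"]["founder_skew"],
        bottleneck_months=cfg["simulation"].get("bottleneck_months"),
    )
    seq = sample_sequencing(sim, seed=seq_seed)
    design = sim.design
    month_ind = design_cfg.individual_timepoint_month
    log.info("simulated %d sites, %d populations", sim.n_sites, len(design.populations))

    sync36 = seq.sync_at(month_ind)
    sync36.write(out / "month36.sync")
    truth = {
        "selected_sites": [
            {"chrom": str(c), "pos": p, "s": s, "sign": g}
            for c, p, s, g in sim.truth.selected_sites
        ],
        "census_series": sim.truth.census_series,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))

    # -- stage 2: site filters --------------------------------------------
    scan_cfg = cfg["scan"]
    filtered = filter_sites(sync36, scan_cfg["maf_min"], scan_cfg["cov_min"])
    key = {(c, int(p)) for c, p in zip(filtered.chroms, filtered.positions)}
    site_mask = np.array(
        [(c, int(p)) in key for c, p in zip(sim.chroms, sim.positions)], dtype=bool
    )
    log.info("site filter: %d of %d sites retained", site_mask.sum(), sim.n_sites)

    # -- stage 3: scans per contrast --------------------------------------
    colors = sorted({p.color for p in design.populations if p.color != CONTROL_COLOR})
    preenings = sorted({p.preening for p in design.populations})
    reps = range(1, design_cfg.n_replicates + 1)
    chroms_f, pos_f = sim.chroms[site_mask], sim.positions[site_mask]
    scan_rows, locus_sets, rep_locus_sets = [], {}, {}
    windows_frames = []
    for color in colors:
        for preen in preenings:
            tgt_pops = [f"{color}_{preen}_r{r}" for r in reps]
            bg_pops = [f"{CONTROL_COLOR}_{preen}_r{r}" for r in reps]
            ref, alt, pops = seq.counts_at(month_ind, tgt_pops + bg_pops)
            ref, alt = ref[site_mask], alt[site_mask]
            nt = len(tgt_pops)
            # per-replicate pFST + per-replicate loci
            for k, r in enumerate(reps):
                stat, p, _ = pfst_sites(
                    ref[:, k], alt[:, k], ref[:, nt + k], alt[:, nt + k],
                    scan_cfg["epsilon"],
                )
                res = ScanResult.from_stats(
                    chroms_f, pos_f, stat, p, f"pfst_{color}_{preen}_r{r}",
                    scan_cfg["top_fraction"], scan_cfg["q_alpha"],
                )
                rep_locus_sets[(color, preen, r)] = call_and_merge_loci(
                    res, sim.chrom_sizes, scan_cfg["top_fraction"],
                    scan_cfg["q_alpha"], scan_cfg["merge_distance"],
                    scan_cfg["outlier_rule"], f"{color}_{preen}_r{r}",
                )
                scan_rows.append(res.sites.assign(test=res.test))
            # replicate-combined ("all") pFST
            stat, p, _ = pfst_sites(
                ref[:, :nt].sum(1), alt[:, :nt].sum(1),
                ref[:, nt:].sum(1), alt[:, nt:].sum(1), scan_cfg["epsilon"],
            )
            res_all = ScanResult.from_stats(
                chroms_f, pos_f, stat, p, f"pfst_{color}_{preen}_all",
                scan_cfg["top_fraction"], scan_cfg["q_alpha"],
            )
            scan_rows.append(res_all.sites.assign(test=res_all.test))
            locus_sets[(color, preen)] = call_and_merge_loci(
                res_all, sim.chrom_sizes, scan_cfg["top_fraction"],
                scan_cfg["q_alpha"], scan_cfg["merge_distance"],
                scan_cfg["outlier_rule"], f"{color}_{preen}",
            )
            win = window_fisher(chroms_f, pos_f, p,
                                scan_cfg["window_size"], scan_cfg["step"])
            windows_frames.append(win.table.assign(test=f"pfst_{color}_{preen}_all"))
            # CMH across replicates
            tables = np.empty((ref.shape[0], nt, 2, 2))
            tables[:, :, 0, 0] = alt[:, :nt]
            tables[:, :, 0, 1] = ref[:, :nt]
            tables[:, :, 1, 0] = alt[:, nt:]
            tables[:, :, 1, 1] = ref[:, nt:]
            stat, p = cmh_sites(tables)
            res_cmh = ScanResult.from_stats(
                chroms_f, pos_f, stat, p, f"cmh_{color}_{preen}",
                scan_cfg["top_fraction"], scan_cfg["q_alpha"],
            )
            scan_rows.append(res_cmh.sites.assign(test=res_cmh.test))
    site_stats = pd.concat(scan_rows, ignore_index=True)
    _write_tsv(site_stats, out / "site_stats.tsv")
    _write_tsv(pd.concat(windows_frames, ignore_index=True), out / "window_stats.tsv")

    # -- stage 4: locus calling, merging, control subtraction -------------
    final_loci: dict = {}
    counts_log = []
    for color in colors:
        pre = locus_sets[(color, "preen")]
        imp = locus_sets.get((color, "impaired"),
                             IntervalSet(np.array([], dtype=object),
                                         np.array([], dtype=np.int64),
                                         np.array([], dtype=np.int64),
                                         sim.chrom_sizes))
        kept = subtract_impaired(pre, imp)
        final_loci[color] = kept
        counts_log.append({
            "color": color, "preening_loci": len(pre), "impaired_loci": len(imp),
            "removed": len(pre) - len(kept), "retained": len(kept),
        })
        pre.to_bed(out / f"loci_{color}_preen.bed")
        imp.to_bed(out / f"loci_{color}_impaired.bed")
        kept.to_bed(out / f"loci_{color}_final.bed")
        for r in reps:
            rep_locus_sets[(color, "preen", r)].to_bed(
                out / f"loci_{color}_preen_r{r}.bed")
    locus_counts = pd.DataFrame(counts_log)
    _write_tsv(locus_counts, out / "locus_counts.tsv")

    # -- stage 5: trajectories at final loci ------------------------------
    months = sorted(list(design_cfg.pooled_timepoints_months) + [month_ind])
    gens = np.array([design_cfg.generations_at(m) for m in months], dtype=float)
    traj_rows, fix_rows = [], []
    slope_groups: dict = {"selected_preen": [], "selected_impaired": [], "random": []}
    n_tp = len(months)
    site_index = {(str(c), int(p)): i
                  for i, (c, p) in enumerate(zip(sim.chroms, sim.positions))}
    for color in colors:
        kept = final_loci[color]
        all_stats = site_stats[site_stats["test"] == f"pfst_{color}_preen_all"]
        idx_by_pos = {(str(r.chrom), int(r.pos)): r.statistic
                      for r in all_stats.itertuples()}
        # most significant site per locus
        chosen = []
        for c, s, e in zip(kept.chroms, kept.starts, kept.ends):
            in_locus = [(idx_by_pos.get((str(c), int(p)), -1.0), int(p))
                        for p in pos_f[(chroms_f == c) & (pos_f > s) & (pos_f <= e)]]
            if in_locus:
                chosen.append((str(c), max(in_locus)[1]))
        for c, p in chosen:
            i = site_index[(c, p)]
            # polarize on summed preen vs control counts at the reference month
            tgt = [f"{color}_preen_r{r}" for r in reps]
            ctl = [f"{CONTROL_COLOR}_preen_r{r}" for r in reps]
            ref36, alt36, _ = seq.counts_at(month_ind, tgt + ctl)
            pol = traj_mod.polarize_sites(
                np.array([ref36[i, :len(tgt)].sum()]), np.array([alt36[i, :len(tgt)].sum()]),
                np.array([ref36[i, len(tgt):].sum()]), np.array([alt36[i, len(tgt):].sum()]),
            )[0]
            for preen, group in (("preen", "selected_preen"),
                                 ("impaired", "selected_impaired")):
                for r in reps:
                    pid = f"{color}_{preen}_r{r}"
                    series = _extract_series(seq, i, pid, months, gens, pol,
                                             f"{c}:{p}")
                    try:
                        ols = traj_mod.fit_slope_ols(series)
                        glm = traj_mod.fit_slope_glm(series)
                    except ValueError:
                        continue
                    state, fidx = traj_mod.score_fixation(series)
                    slope_groups[group].append(ols.slope)
                    traj_rows.append({
                        "site": f"{c}:{p}", "color": color, "preening": preen,
                        "replicate": r, "polarity": pol,
                        "ols_slope": ols.slope, "ols_p": ols.p_value,
                        "glm_slope": glm.slope, "glm_p": glm.p_value,
                        "glm_separated": glm.separated,
                        "fixation": state,
                    })
                    fix_rows.append({"color": color, "preening": preen,
                                     "replicate": r, "site": f"{c}:{p}",
                                     "state": state, "first_index": fidx})
    # random-site slope baseline in the selected (preen) populations
    rng_rand = np.random.default_rng(perm_seed)
    filtered_idx = np.flatnonzero(site_mask)
    n_rand = min(40, filtered_idx.size)
    for i in rng_rand.choice(filtered_idx, size=n_rand, replace=False):
        pid = f"{colors[0]}_preen_r1"
        series = _extract_series(seq, int(i), pid, months, gens, "alt",
                                 f"{sim.chroms[i]}:{sim.positions[i]}")
        try:
            slope_groups["random"].append(traj_mod.fit_slope_ols(series).slope)
        except ValueError:
            pass
    traj_table = pd.DataFrame(traj_rows)
    _write_tsv(traj_table, out / "trajectory_fits.tsv")
    fix_table = pd.DataFrame(fix_rows)
    _write_tsv(fix_table, out / "fixation_table.tsv")
    groups_ok = {k: v for k, v in slope_groups.items() if len(v) >= 2}
    if len(groups_ok) >= 2:
        tukey = traj_mod.compare_slopes_tukey(groups_ok)
        _write_tsv(tukey, out / "slope_tukey.tsv")
    fix_curves = {}
    if fix_rows:
        for preen in preenings:
            sub = fix_table[fix_table["preening"] == preen]
            curve = traj_mod.cumulative_fixations(
                list(zip(sub["state"], sub["first_index"])), n_tp)
            fix_curves[preen] = curve.tolist()
        (out / "fixation_curves.json").write_text(json.dumps(
            {"months": months, **fix_curves}, indent=1))

    # -- stage 6: replicate overlap ---------------------------------------
    overlap_out: dict = {}
    for color in colors:
        sets = [rep_locus_sets[(color, "preen", r)] for r in reps]
        if all(len(s) for s in sets[:2]):
            perm = permutation_overlap_test(
                sets[0], sets[1], cfg["overlap"]["n_permutations"], seed=perm_seed)
            overlap_out[f"{color}_r1_vs_r2"] = {
                "observed": perm.observed, "null_mean": perm.null_mean,
                "p": perm.p_value,
            }
        if len(sets) >= 2:
            hist = replicate_sharing_histogram(sets)
            overlap_out[f"{color}_sharing_histogram"] = hist.tolist()
    if len(colors) >= 2:
        def _rates(color):
            sets = [rep_locus_sets[(color, "preen", r)] for r in reps]
            total = sum(len(s) for s in sets)
            hist = replicate_sharing_histogram(sets) if total else np.zeros(len(reps), int)
            shared = int(sum(hist[1:]))
            return total, shared
        t1, t2 = _rates(colors[0]), _rates(colors[1])
        if t1[0] and t2[0]:
            odds, p = fisher_exact_overlap(t1, t2)
            overlap_out["overlap_rate_fisher"] = {
                "treatments": colors[:2], "tables": [t1, t2], "odds": odds, "p": p}
    (out / "overlap.json").write_text(json.dumps(overlap_out, indent=1))

    # -- stage 7: Ne summaries --------------------------------------------
    ne_rows = []
    first_m, last_m = months[0], months[-2] if months[-1] == month_ind else months[-1]
    t_gens = design_cfg.generations_at(last_m) - design_cfg.generations_at(first_m)
    for pop in design.populations:
        census = list(sim.truth.census_series[pop.pop_id].values())
        hm = popgen.harmonic_mean_ne(census)
        a0, d0 = seq.pooled[(pop.pop_id, first_m)]
        a1, d1 = seq.pooled[(pop.pop_id, last_m)]
        ok = (d0[site_mask] > 0) & (d1[site_mask] > 0)
        f0 = a0[site_mask][ok] / d0[site_mask][ok]
        f1 = a1[site_mask][ok] / d1[site_mask][ok]
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            tn = popgen.temporal_ne(
                f0, f1, t_gens, design_cfg.sample_cap, design_cfg.sample_cap,
                float(d0[site_mask][ok].mean()), float(d1[site_mask][ok].mean()))
        ne_rows.append({
            "population": pop.pop_id, "harmonic_mean_ne": hm,
            "temporal_ne": tn.ne if np.isfinite(tn.ne) else "unbounded",
            "fc_mean": tn.fc_mean, "n_sites": tn.n_sites,
        })
    _write_tsv(pd.DataFrame(ne_rows), out / "ne_table.tsv")

    # -- manifest and report ----------------------------------------------
    manifest = {
        "config": cfg,
        "seeds": {"root": cfg["seed"], "sim": sim_seed, "seq": seq_seed,
                  "perm": perm_seed},
        "stages": ["simulate", "filter", "scan", "loci", "trajectories",
                   "overlap", "ne"],
        "outputs": {},
    }
    for f in sorted(out.iterdir()):
        if f.name not in ("manifest.json", "report.md") and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    make_report(out, make_plots=cfg.get("make_plots", False))
    return manifest


def _extract_series(seq, site_idx, pop_id, months, gens, polarity, site_id):
    """Build one tracked-allele trajectory from the sequenced experiment."""
    cfg = seq.sim.design.config
    counts = np.zeros(len(months), dtype=np.int64)
    totals = np.zeros(len(months), dtype=np.int64)
    for t, m in enumerate(months):
        if m == cfg.individual_timepoint_month:
            dos = seq.individuals[pop_id]
            alt = int(dos[:, site_idx].sum())
            tot = 2 * dos.shape[0]
        else:
            a, d = seq.pooled[(pop_id, m)]
            alt, tot = int(a[site_idx]), int(d[site_idx])
        counts[t] = alt if polarity == "alt" else tot - alt
        totals[t] = tot
    return traj_mod.TrajectorySeries(site_id, pop_id, gens, counts, totals, polarity)


def make_report(run_dir, make_plots: bool = False) -> Path:
    """Render a markdown report from the stage outputs in ``run_dir``.

    Missing stage outputs are reported as gaps, not failures.
    """
    run_dir = Path(run_dir)
    lines = ["# lousescan run report", ""]

    def section(title, fname, render):
        lines.append(f"## {title}\n")
        path = run_dir / fname
        if not path.exists():
            lines.append(f"_missing: {fname}_\n")
            return None
        return render(path)

    def tsv_table(path, n=12):
        try:
            df = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError:
            lines.append("_no records_\n")
            return None
        if df.empty:
            lines.append("_no records_\n")
            return df
        lines.append(df.head(n).to_markdown(index=False))
        if len(df) > n:
            lines.append(f"\n_... {len(df)} rows total_")
        lines.append("")
        return df

    section("Simulation truth", "truth.json", lambda p: lines.append(
        f"{len(json.loads(p.read_text())['selected_sites'])} ground-truth selected sites\n"))
    section("Site statistics", "site_stats.tsv", tsv_table)
    section("Window statistics", "window_stats.tsv", tsv_table)

    def loci_section(path):
        df = tsv_table(path)
        if df is not None and not df.empty and df["retained"].sum() == 0:
            lines.append("**No loci passed the outlier thresholds.**\n")
        return df
    section("Locus bookkeeping (preening / impaired / retained)",
            "locus_counts.tsv", loci_section)
    section("Trajectory fits", "trajectory_fits.tsv", tsv_table)
    section("Slope comparison (Tukey HSD)", "slope_tukey.tsv", tsv_table)
    section("Cumulative fixation curves", "fixation_curves.json",
            lambda p: lines.append("```json\n" + p.read_text() + "\n```\n"))
    section("Replicate sharing and overlap", "overlap.json",
            lambda p: lines.append("```json\n" + p.read_text() + "\n```\n"))
    section("Effective population size", "ne_table.tsv", tsv_table)

    if make_plots:
        _render_plots(run_dir, lines)
    report = run_dir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report


def _render_plots(run_dir: Path, lines: list) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stats_path = run_dir / "site_stats.tsv"
    if stats_path.exists():
        df = pd.read_csv(stats_path, sep="\t")
        tests = [t for t in df["test"].unique() if t.endswith("_all")]
        if tests:
            sub = df[df["test"] == tests[0]]
            fig, ax = plt.subplots(figsize=(8, 3))
            x = np.arange(len(sub))
            ax.scatter(x, -np.log10(np.clip(sub["q"], 1e-300, 1)), s=4,
                       c=pd.factorize(sub["chrom"])[0] % 2, cmap="coolwarm")
            ax.set_xlabel("site rank"); ax.set_ylabel("-log10 q")
            ax.set_title(tests[0])
            fig.tight_layout(); fig.savefig(run_dir / "manhattan.png", dpi=110)
            plt.close(fig)
            lines.append("![manhattan](manhattan.png)\n")
    fix_path = run_dir / "fixation_curves.json"
    if fix_path.exists():
        curves = json.loads(fix_path.read_text())
        months = curves.pop("months")
        fig, ax = plt.subplots(figsize=(5, 3))
        for name, curve in curves.items():
            ax.step(months, curve, where="post", label=name)
        ax.set_xlabel("month"); ax.set_ylabel("cumulative fixations + losses")
        ax.legend()
        fig.tight_layout(); fig.savefig(run_dir / "fixation_curves.png", dpi=110)
        plt.close(fig)
        lines.append("![fixations](fixation_curves.png)\n")
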
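"""End-to-end orchestration: simulate datasets and compare two conditions.

`run_simulate` writes a complete synthetic two-condition dataset (matrices in
the triplet+bins dialect, feature BEDs, DE table, manifest).  `run_compare`
re-reads such a dataset (or any real data in the same formats), executes the
full balance → O/E → compartments → insulation/TADs/DI → aggregates → decay →
feature-enrichment chain for both conditions and writes every module's output
plus a condition-level summary table.  Identical config ⇒ identical outputs.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregates, compartments, domains, features, io, matrix, simulate
from .exceptions import PipelineError

logger = logging.getLogger("hicarch")

DEFAULTS = {
    "outdir": "hicarch_run",
    "seed": 0,
    "genome": {"chrom": "chrS", "length_bp": 50_000_000, "bin_size": 25_000},
    "truth": {"n_tads": 20, "delta_comp": 0.4, "delta_tad": 0.6, "lam": 1.0,
              "alpha": -1.0, "depth": 1e6},
    "relax": {"comp": 0.9, "tad": 0.7, "loop": 0.7},
    "features": {"n_up": 100, "n_down": 60, "n_non": 340,
                 "q_between": 0.6, "q_background": 0.2},
    "balance": {"max_iter": 200, "tol": 1e-4, "mask_frac": 0.02},
    "compartments": {"min_sep_bins": 2},
    "insulation": {"square_span_bp": 500_000, "norm_span_bp": 2_000_000,
                   "delta_span_bp": 100_000, "min_strength": 0.3,
                   "smooth_span_bp": 100_000},
    "tads": {"min_tad_bins": 3, "stable_tol_bp": 50_000},
    "di": {"window_bp": 2_000_000},
    "aggregate": {"halo_bins": 5, "flank_bp": 500_000, "out_size": 41},
    "decay": {"min_dist_bp": None, "short_max_bp": 500_000,
              "long_min_bp": 4_000_000},
    "de": {"fdr_max": 0.05, "lfc_min": 1.5},
    "inputs": {
        "chrom": None,
        "cond1_triplet": None, "cond1_bins": None,
        "cond2_triplet": None, "cond2_bins": None,
        "genes_bed": None, "de_tsv": None,
        "enh_esc_bed": None, "enh_2c_bed": None,
        "loops_bedpe": None, "ep_bedpe": None,
        "boundaries_bed": None, "orientation_bedgraph": None,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def make_config(override: dict | None = None) -> dict:
    return _merge(DEFAULTS, override or {})


def load_config(path) -> dict:
    with open(path) as fh:
        return make_config(yaml.safe_load(fh) or {})


def save_config(cfg: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _dataset_config(outdir) -> dict:
    """Input paths pointing at a run_simulate output directory."""
    d = str(outdir)
    return {"inputs": {
        "chrom": None,
        "cond1_triplet": f"{d}/cond1.matrix.tsv", "cond1_bins": f"{d}/cond1.bins.bed",
        "cond2_triplet": f"{d}/cond2.matrix.tsv", "cond2_bins": f"{d}/cond2.bins.bed",
        "genes_bed": f"{d}/genes.bed", "de_tsv": f"{d}/de.tsv",
        "enh_esc_bed": f"{d}/enhancers_esc.bed", "enh_2c_bed": f"{d}/enhancers_2c.bed",
        "loops_bedpe": f"{d}/loops.bedpe", "ep_bedpe": f"{d}/ep_pairs.bedpe",
        "boundaries_bed": None,
        "orientation_bedgraph": f"{d}/comp_signs.bedgraph",
    }}


def run_simulate(cfg: dict) -> dict:
    """Write a synthetic two-condition dataset; returns a manifest dict."""
    cfg = make_config(cfg)
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    g = simulate.GenomeSpec(seed=int(cfg["seed"]), **cfg["genome"])
    truth = simulate.default_truth(g, **cfg["truth"])
    relax = cfg["relax"]
    m1, m2, truth2 = simulate.simulate_condition_pair(
        g, truth, relax_comp=relax["comp"], relax_tad=relax["tad"],
        relax_loop=relax["loop"],
    )
    fs = simulate.simulate_features(
        g, truth, simulate.FeatureTruth(**cfg["features"])
    )

    io.write_matrix(m1, out / "cond1.matrix.tsv", out / "cond1.bins.bed")
    io.write_matrix(m2, out / "cond2.matrix.tsv", out / "cond2.bins.bed")
    io.write_bed(fs.genes, out / "genes.bed")
    io.write_tsv(fs.de, out / "de.tsv")
    io.write_bed(fs.enhancers["esc"], out / "enhancers_esc.bed",
                 cols=("chrom", "start", "end", "name", "cls"))
    io.write_bed(fs.enhancers["2c"], out / "enhancers_2c.bed",
                 cols=("chrom", "start", "end", "name", "cls"))
    if len(fs.enhancers["super"]):
        io.write_bed(fs.enhancers["super"], out / "enhancers_super.bed",
                     cols=("chrom", "start", "end", "name", "cls"))
    pd.DataFrame({
        "chrom": g.chrom, "start": fs.boundaries_bp,
        "end": fs.boundaries_bp + 1,
    }).to_csv(out / "planted_boundaries.bed", sep="\t", header=False, index=False)

    bs = g.bin_size
    tb = truth.boundary_bins()
    pd.DataFrame({"chrom": g.chrom, "start": tb * bs, "end": tb * bs + 1}) \
        .to_csv(out / "truth_boundaries.bed", sep="\t", header=False, index=False)
    pd.DataFrame(
        [(g.chrom, a * bs, b * bs) for a, b in truth.tads]
    ).to_csv(out / "truth_tads.bed", sep="\t", header=False, index=False)
    io.write_bedgraph(g.chrom, bs, truth.comp_signs, out / "comp_signs.bedgraph")

    def _bedpe(pairs, path):
        pd.DataFrame(
            [(g.chrom, a * bs, (a + 1) * bs, g.chrom, b * bs, (b + 1) * bs)
             for a, b in pairs]
        ).to_csv(path, sep="\t", header=False, index=False)

    _bedpe(truth.loops, out / "loops.bedpe")
    _bedpe(truth.ep_pairs, out / "ep_pairs.bedpe")

    manifest = {
        "seed": int(cfg["seed"]),
        "genome": dict(cfg["genome"]),
        "truth": {**cfg["truth"], "n_loops": len(truth.loops),
                  "n_ep_pairs": len(truth.ep_pairs)},
        "relax": dict(cfg["relax"]),
        "features": dict(cfg["features"]),
    }
    io.write_json(manifest, out / "manifest.json")
    logger.info("simulated dataset written to %s", out)
    return manifest


def _load_orientation(path, n_bins, bin_size):
    if path is None:
        return None
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    track = np.full(n_bins, np.nan)
    idx = (df["start"] // bin_size).to_numpy()
    ok = (idx >= 0) & (idx < n_bins)
    track[idx[ok].astype(int)] = df["value"].to_numpy()[ok]
    return track


def analyze_condition(m_raw, cfg: dict, orientation=None) -> dict:
    """Single-condition chain: balance, O/E, compartments, domains, decay."""
    bal = matrix.ice_balance(m_raw, **cfg["balance"])
    exp = matrix.expected_by_distance(bal)
    oe = matrix.oe_transform(bal, exp)
    prof = compartments.compute_pc1(oe, orientation_track=orientation)
    strength = compartments.compartment_strength(
        oe, prof, min_sep_bins=cfg["compartments"]["min_sep_bins"])
    ins = domains.insulation_normalize(
        domains.insulation_raw(bal, cfg["insulation"]["square_span_bp"]),
        cfg["insulation"]["norm_span_bp"])
    bounds = domains.call_boundaries(
        ins, cfg["insulation"]["delta_span_bp"], cfg["insulation"]["min_strength"],
        cfg["insulation"]["smooth_span_bp"])
    tads = domains.tads_from_boundaries(
        bounds, m_raw.n_bins, cfg["tads"]["min_tad_bins"])
    tad_strengths = np.array([domains.tad_strength(oe, t) for t in tads.intervals])
    di = domains.directionality_index(bal, cfg["di"]["window_bp"])
    inter = (domains.inter_tad_frequency(m_raw, tads) if len(tads) >= 2 else None)
    decay = matrix.decay_curve(m_raw, cfg["decay"]["min_dist_bp"])
    return {
        "raw": m_raw, "balanced": bal, "expected": exp, "oe": oe,
        "pc1": prof, "compartment_strength": strength,
        "insulation": ins, "boundaries": bounds, "tads": tads,
        "tad_strengths": tad_strengths, "di": di, "inter_tad": inter,
        "decay": decay,
    }


def run_compare(cfg: dict) -> pd.DataFrame:
    """Two-condition comparison; writes all outputs, returns the summary."""
    cfg = make_config(cfg)
    out = Path(cfg["outdir"])
    inputs = cfg["inputs"]

    for key in ("cond1_triplet", "cond1_bins", "cond2_triplet", "cond2_bins"):
        p = inputs.get(key)
        if p is None or not Path(p).exists():
            raise PipelineError("config", f"missing matrix input {key!r}: {p}")
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            (out / "FAILED").write_text(f"{name}: {exc}\n")
            raise PipelineError(name, str(exc)) from exc

    bins1 = io.read_bins(inputs["cond1_bins"])
    chrom = inputs["chrom"] or str(bins1["chrom"].iloc[0])
    m1 = stage("read", io.read_matrix, inputs["cond1_triplet"],
               inputs["cond1_bins"], chrom)
    m2 = stage("read", io.read_matrix, inputs["cond2_triplet"],
               inputs["cond2_bins"], chrom)
    orientation = _load_orientation(inputs.get("orientation_bedgraph"),
                                    m1.n_bins, m1.bin_size)

    r1 = stage("cond1", analyze_condition, m1, cfg, orientation)
    # orient condition 2 by condition 1's PC1 so switch classes are comparable
    r2 = stage("cond2", analyze_condition, m2, cfg,
               orientation if orientation is not None else r1["pc1"].pc1)

    switches = stage("switches", compartments.classify_switches,
                     r1["pc1"], r2["pc1"])

    agg = cfg["aggregate"]
    results = {}
    for label, r in (("cond1", r1), ("cond2", r2)):
        io.write_bedgraph(chrom, m1.bin_size, r["pc1"].pc1,
                          out / f"{label}.pc1.bedgraph")
        io.write_bedgraph(chrom, m1.bin_size, r["insulation"].normalized,
                          out / f"{label}.insulation.bedgraph")
        io.write_bedgraph(chrom, m1.bin_size, r["di"].di,
                          out / f"{label}.di.bedgraph")
        b = r["boundaries"]
        pd.DataFrame({"chrom": chrom, "start": b.positions_bp(),
                      "end": b.positions_bp() + m1.bin_size,
                      "strength": b.strengths}) \
            .to_csv(out / f"{label}.boundaries.bed", sep="\t",
                    header=False, index=False)
        pd.DataFrame([(chrom, a * m1.bin_size, bb * m1.bin_size)
                      for a, bb in r["tads"].intervals]) \
            .to_csv(out / f"{label}.tads.bed", sep="\t", header=False, index=False)
        io.write_decay(r["decay"], out / f"{label}.decay.tsv")
        io.write_expected(r["expected"], out / f"{label}.expected.tsv")
        if r["inter_tad"] is not None:
            k = len(r["tads"])
            rows = [(p, q, r["inter_tad"][p, q])
                    for p in range(k) for q in range(p + 1, k)]
            io.write_tsv(pd.DataFrame(rows, columns=["tad_p", "tad_q", "freq"]),
                         out / f"{label}.inter_tad.tsv")

    stable, only1, only2 = stage("stable_tads", domains.stable_tads,
                                 r1["tads"], r2["tads"],
                                 cfg["tads"]["stable_tol_bp"])
    for name, ts in (("stable", stable), ("cond1_only", only1),
                     ("cond2_only", only2)):
        pd.DataFrame([(chrom, a * m1.bin_size, b * m1.bin_size)
                      for a, b in ts.intervals]) \
            .to_csv(out / f"tads.{name}.bed", sep="\t", header=False, index=False)

    def _mean_pair_strength(r, pairs):
        vals = [aggregates.pair_strength(r["oe"], p, agg["halo_bins"])
                for p in pairs]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    loops = ep = None
    if inputs.get("loops_bedpe") and Path(inputs["loops_bedpe"]).exists():
        loops = aggregates.anchor_pairs_from_bedpe(
            io.read_bedpe(inputs["loops_bedpe"]), chrom, m1.bin_size)
    if inputs.get("ep_bedpe") and Path(inputs["ep_bedpe"]).exists():
        ep = aggregates.anchor_pairs_from_bedpe(
            io.read_bedpe(inputs["ep_bedpe"]), chrom, m1.bin_size)

    for label, r in (("cond1", r1), ("cond2", r2)):
        if len(r["boundaries"]):
            bagg = stage("aggregate", aggregates.boundary_aggregate,
                         r["oe"], r["boundaries"], agg["flank_bp"])
            pd.DataFrame(bagg.values).to_csv(
                out / f"{label}.boundary_aggregate.tsv", sep="\t",
                header=False, index=False, float_format="%.6g")
            io.write_json({"n_windows": bagg.n_windows, "source": bagg.source,
                           "out_size": bagg.values.shape[0]},
                          out / f"{label}.boundary_aggregate.json")

    dec = cfg["decay"]
    summary_rows = []

    def add(name, v1, v2):
        summary_rows.append({
            "statistic": name, "cond1": v1, "cond2": v2,
            "diff": (v2 - v1) if np.isfinite(v1) and np.isfinite(v2)
            else float("nan"),
        })

    ins_at = {}
    for label, r in (("cond1", r1), ("cond2", r2)):
        b = r1["boundaries"].bins  # condition-1 boundaries as common reference
        vals = r["insulation"].normalized[b] if b.size else np.array([np.nan])
        ins_at[label] = float(np.nanmean(vals))

    add("compartment_strength",
        r1["compartment_strength"], r2["compartment_strength"])
    add("n_tads", float(len(r1["tads"])), float(len(r2["tads"])))
    add("mean_tad_strength", float(np.nanmean(r1["tad_strengths"])),
        float(np.nanmean(r2["tad_strengths"])))
    add("mean_boundary_insulation", ins_at["cond1"], ins_at["cond2"])
    add("inter_tad_total_freq",
        *(float(np.triu(r["inter_tad"], 1).sum())
          if r["inter_tad"] is not None else float("nan")
          for r in (r1, r2)))
    if loops:
        add("mean_loop_strength", _mean_pair_strength(r1, loops),
            _mean_pair_strength(r2, loops))
    if ep:
        add("mean_ep_strength", _mean_pair_strength(r1, ep),
            _mean_pair_strength(r2, ep))
    add("decay_short_mass",
        *(r["decay"].mass_between(0, dec["short_max_bp"]) for r in (r1, r2)))
    add("decay_long_mass",
        *(r["decay"].mass_between(dec["long_min_bp"], np.inf) for r in (r1, r2)))
    for cls, frac in switches.fractions.items():
        add(f"switch_fraction[{cls}]", frac, frac)

    pd.DataFrame([
        {"class": c, "fraction": v} for c, v in switches.fractions.items()
    ]).pipe(io.write_tsv, out / "switches.tsv")

    # ---- feature statistics (optional inputs) -------------------------------
    if inputs.get("genes_bed") and inputs.get("de_tsv") \
            and Path(inputs["genes_bed"]).exists():
        genes = io.read_bed(inputs["genes_bed"])
        de = io.read_de_table(inputs["de_tsv"])
        cls = features.classify_genes(de, **cfg["de"])
        genes = genes.merge(
            pd.DataFrame({"name": de["gene"], "cls_de": cls}),
            on="name", how="left")
        genes["cls"] = genes["cls_de"].fillna("non")

        for tag, key in (("esc", "enh_esc_bed"), ("2c", "enh_2c_bed")):
            path = inputs.get(key)
            if path and Path(path).exists():
                targets = io.read_bed(path)
                dists = features.nearest_distance(genes, targets)
                by_cls = {c: dists[(genes["cls"] == c).to_numpy()]
                          for c in ("up", "down", "non")}
                curves, ks = features.cumulative_curves_ks(by_cls)
                io.write_tsv(curves, out / f"distance_curves_{tag}.tsv")
                io.write_tsv(ks, out / f"ks_{tag}.tsv")

        per_gene, fracs = features.annotate_switch_overlap(
            genes, switches.classes, m1.bin_size)
        io.write_tsv(fracs, out / "gene_switch_fractions.tsv")

        if inputs.get("boundaries_bed") and Path(inputs["boundaries_bed"]).exists():
            bdf = io.read_bed(inputs["boundaries_bed"],
                              names=("chrom", "start", "end"))
            bpos = {c: g["start"].to_numpy() for c, g in bdf.groupby("chrom")}
        else:
            bpos = {chrom: r1["boundaries"].positions_bp()}
        if inputs.get("enh_2c_bed") and Path(inputs["enh_2c_bed"]).exists():
            enh2c = io.read_bed(inputs["enh_2c_bed"])
            enr = features.boundary_enrichment(
                genes, enh2c, bpos,
                {chrom: m1.n_bins * m1.bin_size})
            io.write_tsv(pd.DataFrame([{
                "gene_class": e.gene_class, "n_genes": e.n_genes,
                "observed": e.observed_count, "control": e.control_count,
                "enrichment": e.enrichment} for e in enr]),
                out / "boundary_enrichment.tsv")

    summary = pd.DataFrame(summary_rows)
    io.write_tsv(summary, out / "summary.tsv")
    logger.info("comparison written to %s", out)
    return summary
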
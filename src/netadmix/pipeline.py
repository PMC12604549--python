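"""Config-driven pipeline driver.

A single YAML config names inputs, enabled stages and a seed; each stage
writes machine-readable tables into its own subdirectory of the run
directory plus a ``<stage>.done`` marker, and appends a log line with its
parameters and input digests. Re-running the same config resumes after
completed stages; outputs are byte-identical for identical config + seed
(floats are serialised with a fixed format and no timestamps enter any
output).

Stage order: simulate, qc, twisst, sitestats, netscore, calibrate, asr.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import asr as asr_mod
from . import calibrate as cal_mod
from . import qc as qc_mod
from . import scoring
from . import sitestats
from . import twisst as twisst_mod
from .network import (
    parse_extended_newick,
    read_extended_newick_file,
    write_extended_newick_file,
)
from .simulate import SimConfig, simulate_gene_trees, simulate_snp_matrix
from .snp import GroupingConfig, SNPMatrix, TraitTable
from .trees import read_newick_file, write_newick_file

__all__ = ["run_pipeline", "PipelineError"]

STAGES = ("simulate", "qc", "twisst", "sitestats", "netscore", "calibrate", "asr")
FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    pass


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer, np.bool_)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def _write_table(df, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


class _Run:
    def __init__(self, config: dict, outdir: Path):
        self.cfg = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.log_path = self.outdir / "pipeline.log"
        self.seed = int(config.get("seed", 0))

    def log(self, stage: str, params: dict, inputs: dict) -> None:
        entry = {
            "stage": stage,
            "params": params,
            "inputs": {k: _digest(v) for k, v in inputs.items()},
        }
        with open(self.log_path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")

    def stage_dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(exist_ok=True)
        return d

    def done_marker(self, stage: str) -> Path:
        return self.outdir / f"{stage}.done"

    def is_done(self, stage: str) -> bool:
        return self.done_marker(stage).exists()

    def mark_done(self, stage: str) -> None:
        self.done_marker(stage).write_text("done\n")


def _preflight(cfg: dict, stages: list) -> None:
    """Fail before any stage runs if a referenced input file is absent."""
    missing = []

    def check(path):
        if path and not Path(path).exists():
            missing.append(str(path))

    inputs = cfg.get("inputs", {})
    if "simulate" in stages:
        check(cfg.get("simulate", {}).get("network"))
    else:
        if any(s in stages for s in ("qc", "twisst", "netscore", "calibrate")):
            check(inputs.get("gene_trees"))
        if "sitestats" in stages:
            check(inputs.get("snp"))
    if any(s in stages for s in ("qc", "twisst", "sitestats")):
        check(inputs.get("grouping"))
    if "netscore" in stages:
        for c in inputs.get("candidates", []):
            check(c)
    if "asr" in stages:
        check(inputs.get("traits"))
        if "calibrate" not in stages:
            check(inputs.get("calibrated_network"))
    if "sitestats" in stages and cfg.get("sitestats", {}).get("species_tree"):
        check(cfg["sitestats"]["species_tree"])
    if missing:
        raise PipelineError(f"missing input files: {sorted(set(missing))}")


def run_pipeline(config_path) -> Path:
    """Execute the enabled stages of a config; returns the run directory."""
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    stages = list(cfg.get("stages", STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    outdir = Path(cfg.get("outdir", config_path.with_suffix("")))
    _preflight(cfg, stages)
    run = _Run(cfg, outdir)
    for stage in STAGES:
        if stage not in stages:
            continue
        if run.is_done(stage):
            continue
        _STAGE_FUNCS[stage](run)
        run.mark_done(stage)
    return run.outdir


# ----------------------------------------------------------------------
def _load_grouping(run: _Run) -> GroupingConfig:
    return GroupingConfig.from_tsv(run.cfg["inputs"]["grouping"])


def _gene_trees_path(run: _Run) -> Path:
    sim_out = run.outdir / "simulate" / "gene_trees.nwk"
    if sim_out.exists():
        return sim_out
    return Path(run.cfg["inputs"]["gene_trees"])


def _retained_trees_path(run: _Run) -> Path:
    qc_out = run.outdir / "qc" / "retained.nwk"
    return qc_out if qc_out.exists() else _gene_trees_path(run)


def _snp_path(run: _Run) -> Path:
    sim_out = run.outdir / "simulate" / "snp.tsv"
    if sim_out.exists():
        return sim_out
    return Path(run.cfg["inputs"]["snp"])


def _load_snp(path: Path) -> SNPMatrix:
    if str(path).endswith(".vcf"):
        return SNPMatrix.from_vcf(path)
    return SNPMatrix.from_tsv(path)


def _stage_simulate(run: _Run) -> None:
    p = dict(run.cfg.get("simulate", {}))
    net_path = p.pop("network")
    net = read_extended_newick_file(net_path)[0]
    cfg = SimConfig(network=net, seed=run.seed, **p)
    res = simulate_gene_trees(cfg)
    snp = simulate_snp_matrix(cfg)
    d = run.stage_dir("simulate")
    write_newick_file(d / "gene_trees_coal.nwk", res.trees_coal)
    write_newick_file(d / "gene_trees.nwk", res.trees_subst)
    snp.to_tsv(d / "snp.tsv")
    _json_dump(res.truth, d / "truth.json")
    run.log("simulate", {**p, "seed": run.seed}, {"network": net_path})


def _stage_qc(run: _Run) -> None:
    p = run.cfg.get("qc", {})
    grouping = _load_grouping(run)
    trees_path = _gene_trees_path(run)
    trees = read_newick_file(trees_path)
    outgroup = grouping.outgroup[0]
    ingroup = [t for t in grouping.all_taxa() if t not in grouping.outgroup]
    report, retained = qc_mod.qc_batch(
        trees,
        ingroup,
        outgroup,
        ratio=p.get("ratio", qc_mod.DEFAULT_RATIO),
        min_outdist=p.get("min_outdist", qc_mod.DEFAULT_MIN_OUTDIST),
    )
    d = run.stage_dir("qc")
    _write_table(report.table, d / "qc_report.tsv")
    write_newick_file(d / "retained.nwk", retained)
    _json_dump(report.counts, d / "qc_counts.json")
    run.log("qc", dict(p), {"gene_trees": trees_path})


def _stage_twisst(run: _Run) -> None:
    p = run.cfg.get("twisst", {})
    grouping = _load_grouping(run)
    trees_path = _retained_trees_path(run)
    trees = read_newick_file(trees_path)
    designation = p.get("designation")
    if designation is not None:
        designation = {k: int(v) for k, v in designation.items()}
    res = twisst_mod.twisst_counts(trees, grouping, designation, seed=run.seed)
    test = twisst_mod.ils_chisq_test(res["minor_count"], res["contra_count"])
    d = run.stage_dir("twisst")
    _write_table(res["table"], d / "weights.tsv")
    _json_dump(
        {k: v for k, v in res.items() if k != "table"}, d / "counts.json"
    )
    _json_dump(test, d / "ils_test.json")
    run.log("twisst", dict(p), {"gene_trees": trees_path})


def _stage_sitestats(run: _Run) -> None:
    p = run.cfg.get("sitestats", {})
    grouping = _load_grouping(run)
    snp_path = _snp_path(run)
    matrix = _load_snp(snp_path)
    matrix = sitestats.filter_snps(
        matrix,
        max_missing=p.get("max_missing", 0.2),
        thin_bp=p.get("thin_bp", 100),
    )
    blocks = p.get("blocks", sitestats.DEFAULT_BLOCKS)
    pops = {name: members for name, members in grouping.groups.items()}
    pops["outgroup"] = grouping.outgroup
    freqs = sitestats.population_frequencies(
        matrix, pops, ploidy=p.get("ploidy", 1)
    )
    D = sitestats.patterson_D(
        freqs["P1"], freqs["P2"], freqs["P3"], freqs["outgroup"], blocks=blocks
    )
    f4 = sitestats.f4_ratio(
        freqs["P1"], freqs["P2"], freqs["P3"], freqs["outgroup"], blocks=blocks
    )
    d = run.stage_dir("sitestats")
    _json_dump(
        {
            "n_sites_retained": matrix.n_sites,
            "D": vars(D),
            "f4_ratio": vars(f4),
        },
        d / "dstats.json",
    )
    sim = sitestats.simple_matching_similarity(matrix)
    _write_table(sim, d / "similarity.tsv")
    sp_tree = p.get("species_tree")
    if sp_tree:
        tree = read_newick_file(sp_tree)[0]
        taxon_freqs = sitestats.population_frequencies(
            matrix,
            {t: [t] for t in tree.leaf_labels},
            ploidy=p.get("ploidy", 1),
        )
        fb = sitestats.f_branch(
            tree,
            taxon_freqs,
            outgroup=grouping.outgroup[0],
            blocks=blocks,
            alpha=p.get("fdr", 0.05),
        )
        _write_table(fb.set_index(["branch", "C"]), d / "fbranch.tsv")
    run.log("sitestats", dict(p), {"snp": snp_path})


def _stage_netscore(run: _Run) -> None:
    p = run.cfg.get("netscore", {})
    grouping = _load_grouping(run) if "grouping" in run.cfg.get("inputs", {}) else None
    trees_path = _retained_trees_path(run)
    trees = read_newick_file(trees_path)
    taxa = sorted({lab for t in trees for lab in t.leaf_labels})
    table = scoring.observed_quartet_cf(
        trees, taxa, max_quartets=p.get("max_quartets"), seed=run.seed
    )
    outgroup = grouping.outgroup[0] if grouping else p.get("outgroup")
    evals_by_rs = {}
    rows = []
    for rs, cand_path in enumerate(run.cfg["inputs"]["candidates"]):
        cands = read_extended_newick_file(cand_path)
        evals = scoring.evaluate_candidates(cands, table, outgroup=outgroup)
        evals_by_rs[rs] = evals
        for i, ev in enumerate(evals):
            rows.append(
                {
                    "resampling": rs,
                    "candidate": i,
                    "h": ev.h,
                    "score": ev.score,
                    "delta": ev.delta,
                    "class": ev.support_class,
                }
            )
    sel = scoring.select_prevailing(evals_by_rs)
    d = run.stage_dir("netscore")
    _write_table(
        pd.DataFrame(rows).set_index(["resampling", "candidate"]),
        d / "evaluations.tsv",
    )
    write_extended_newick_file(d / "selected.enewick", sel["selected"])
    _json_dump(
        {"h": sel["h"], "fallback": sel["fallback"],
         "n_selected": len(sel["selected"])},
        d / "selection.json",
    )
    run.log("netscore", dict(p), {"gene_trees": trees_path})


def _stage_calibrate(run: _Run) -> None:
    p = run.cfg.get("calibrate", {})
    trees_path = _retained_trees_path(run)
    trees = read_newick_file(trees_path)
    sel_path = run.outdir / "netscore" / "selected.enewick"
    if sel_path.exists():
        net = read_extended_newick_file(sel_path)[0]
    else:
        net = read_extended_newick_file(run.cfg["inputs"]["network"])[0]
    dbar, counts = cal_mod.mean_pairwise_distances(trees, taxa=net.leaves)
    problem = cal_mod.CalibrationProblem(
        network=net,
        dbar=dbar,
        p_init=p.get("p_init", 1.0),
        w=p.get("w"),
        multistarts=p.get("multistarts", 8),
        seed=run.seed,
    )
    cal = cal_mod.calibrate(problem)
    check = cal_mod.ultrametric_check(cal.network)
    d = run.stage_dir("calibrate")
    write_extended_newick_file(d / "calibrated.enewick", [cal.network])
    _write_table(dbar, d / "mean_distances.tsv")
    _json_dump(
        {
            "p": cal.p,
            "objective": cal.objective,
            "distance_term": cal.distance_term,
            "penalty_term": cal.penalty_term,
            "w": cal.w,
            "converged": cal.converged,
            "ultrametric": check,
            "ages": {str(k): v for k, v in cal.ages.items()},
        },
        d / "calibration.json",
    )
    run.log("calibrate", dict(p), {"gene_trees": trees_path})


def _stage_asr(run: _Run) -> None:
    p = run.cfg.get("asr", {})
    cal_path = run.outdir / "calibrate" / "calibrated.enewick"
    if not cal_path.exists():
        cal_path = Path(run.cfg["inputs"]["calibrated_network"])
    net = read_extended_newick_file(cal_path)[0]
    traits_path = run.cfg["inputs"]["traits"]
    traits = TraitTable.from_tsv(traits_path)
    names = p.get("traits")
    results = asr_mod.reconstruct_all(net, traits, trait_names=names)
    d = run.stage_dir("asr")
    summary = {}
    for name, res in results.items():
        _write_table(res.posteriors, d / f"asr_{name}.tsv")
        summary[name] = {"alpha": res.alpha, "loglik": res.loglik}
    _json_dump(summary, d / "asr_summary.json")
    run.log("asr", dict(p), {"network": cal_path, "traits": traits_path})


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "twisst": _stage_twisst,
    "sitestats": _stage_sitestats,
    "netscore": _stage_netscore,
    "calibrate": _stage_calibrate,
    "asr": _stage_asr,
}
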
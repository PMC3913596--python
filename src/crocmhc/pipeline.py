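"""End-to-end orchestration: validate -> annotate -> tsp -> diversity ->
selection -> recombination -> phylo -> report.

A single global seed expands to per-stage seeds by a fixed counter
scheme (``seed + 1000 * stage_index``) so stages rerun in isolation
reproduce the full-pipeline results.  The run manifest snapshots the
config, the seeds and a sha256 per written file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clone_validation import validate_reads
from .diversity import mean_dn_ds, nei_gojobori, pairwise_differences
from .orf_annotation import annotate_variants
from .recombination import (composition_scan, consensus_recombination_call,
                            estimate_rho_theta, maxchi_scan, triplet_scan)
from .seq_model import (Alignment, read_fasta_with_metadata, read_taxonomy,
                        write_results)
from .tsp_detection import detect_tsps, tally_tsps, translations_from_variants

log = logging.getLogger("crocmhc")

STAGES = ("validate", "annotate", "tsp", "diversity", "selection",
          "recombination", "phylo")


@dataclass
class RunManifest:
    config: dict
    seeds: dict = field(default_factory=dict)
    version: str = __version__
    file_hashes: dict = field(default_factory=dict)

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.file_hashes[path.name] = digest

    def write(self, path: Path) -> None:
        payload = {"config": self.config, "seeds": self.seeds,
                   "version": self.version, "file_hashes": self.file_hashes}
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def stage_seed(seed: int, stage: str) -> int:
    return seed + 1000 * STAGES.index(stage)


def run_all(config: dict, out_dir: str | Path) -> RunManifest:
    """Run the analysis stages listed in ``config`` on a clone dataset.

    Required config keys: reads, meta, taxonomy (paths), chain (DA|DB),
    exon_target, seed.  Optional: skip (list of stage names),
    redundancy_bp, selection (settings dict), bootstrap_reps.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    skip = set(config.get("skip", []))
    manifest = RunManifest(config=dict(config))
    manifest.seeds = {s: stage_seed(seed, s) for s in STAGES}
    log.info("thresholds: min support 2 clones or 2 individuals; "
             "redundancy <%s bp; PP cutoffs 0.95/0.99; consensus >=2 "
             "detectors, score >60; alpha 0.05 Bonferroni",
             config.get("redundancy_bp", 3))

    for key in ("reads", "meta", "taxonomy"):
        if key not in config or not Path(config[key]).exists():
            raise FileNotFoundError(
                f"stage validate: missing input {key!r} "
                f"({config.get(key, '<unset>')})")

    taxonomy = read_taxonomy(config["taxonomy"])
    reads = read_fasta_with_metadata(config["reads"], config["meta"], taxonomy)
    exon_target = config.get("exon_target", "IIb_ex3")
    reads = [r for r in reads if r.exon_target == exon_target]
    chain = config.get("chain", "DB")

    tables: dict[str, pd.DataFrame] = {}
    trees: dict[str, str] = {}
    fastas: dict[str, list] = {}

    # validate
    variants, rejections = validate_reads(
        reads, chain=chain, redundancy_bp=int(config.get("redundancy_bp", 3)),
        taxonomy=taxonomy)
    tables["rejected"] = pd.DataFrame(
        [{"seq": r.seq, "rule": r.rule, "evidence": r.evidence}
         for r in rejections], columns=["seq", "rule", "evidence"])

    # annotate
    if "annotate" not in skip:
        variants = annotate_variants(variants, exon_target)
    fastas["variants"] = variants
    tables["functionality"] = pd.DataFrame(
        [{"name": v.name, "functionality": v.functionality,
          "reasons": ";".join(v.reasons)} for v in variants],
        columns=["name", "functionality", "reasons"])

    # tsp
    if "tsp" not in skip:
        translated = translations_from_variants({exon_target: variants})
        clusters = detect_tsps(translated)
        tables["tsp_tally"] = tally_tsps(clusters, taxonomy)

    aln = None
    lengths = {len(v.seq) for v in variants}
    if len(lengths) == 1 and variants:
        aln = Alignment([(v.name, v.seq) for v in variants], kind="codon"
                        if next(iter(lengths)) % 3 == 0 else "nucleotide")

    # diversity
    if "diversity" not in skip and aln is not None and len(aln) >= 2:
        diffs = pairwise_differences(aln)
        tables["pairwise"] = pd.DataFrame(diffs, index=aln.names,
                                          columns=aln.names).reset_index()
        if aln.kind == "codon":
            pairs = nei_gojobori(aln)
            dn, ds = mean_dn_ds(pairs)
            tables["dnds"] = pd.DataFrame(
                [{"pair": f"{p.seq_a}|{p.seq_b}", "sd": p.sd, "nd": p.nd,
                  "S": p.S_sites, "N": p.N_sites, "dS": p.dS, "dN": p.dN}
                 for p in pairs])
            tables["dnds_summary"] = pd.DataFrame(
                [{"mean_dN": dn, "mean_dS": ds}])

    # selection
    if "selection" not in skip and aln is not None and aln.kind == "codon" \
            and len(aln) >= 3:
        from .selection import McmcSettings, site_omega_mcmc
        sel_cfg = dict(config.get("selection", {}))
        sel_cfg.setdefault("iterations", 2000)
        sel_cfg.setdefault("burn_in", 500)
        sel_cfg.setdefault("thinning", 5)
        sel_cfg["seed"] = stage_seed(seed, "selection")
        run = site_omega_mcmc(aln, McmcSettings(**sel_cfg),
                              pbr_sites=config.get("pbr_sites"))
        tables["site_posteriors"] = pd.DataFrame(
            [{"codon_site": p.codon_site, "omega_mean": p.omega_mean,
              "hpd_low": p.hpd_low, "hpd_high": p.hpd_high,
              "pp_positive": p.pp_positive, "is_pbr": p.is_pbr}
             for p in run.posteriors])

    # recombination
    if "recombination" not in skip and aln is not None and len(aln) >= 4:
        rec_seed = stage_seed(seed, "recombination")
        perms = int(config.get("permutations", 200))
        detectors = {
            "maxchi": maxchi_scan(aln, permutations=perms, seed=rec_seed),
            "triplet": triplet_scan(aln, permutations=perms, seed=rec_seed + 1),
            "composition": composition_scan(aln),
        }
        calls = consensus_recombination_call(detectors)
        tables["recomb_calls"] = pd.DataFrame(
            [{"recombinant": c.recombinant, "parents": "|".join(c.parents),
              "breakpoint": f"{c.breakpoint[0]}-{c.breakpoint[1]}",
              "detectors": ",".join(sorted(c.detectors)),
              "score": c.consensus_score} for c in calls],
            columns=["recombinant", "parents", "breakpoint", "detectors", "score"])
        est = estimate_rho_theta(aln)
        tables["rho_theta"] = pd.DataFrame(
            [{"rho": est.rho, "theta": est.theta, "note": est.ratio_note}])

    # phylo
    if "phylo" not in skip and aln is not None and len(aln) >= 4:
        from .phylo import bootstrap_support, model_select
        model, sel_table = model_select(aln)
        tables["model_selection"] = pd.DataFrame(
            [{k: row[k] for k in ("model", "lnL", "k", "BIC", "AIC",
                                  "gamma_alpha")} for row in sel_table])
        try:
            tree = bootstrap_support(aln, model,
                                     reps=int(config.get("bootstrap_reps", 100)),
                                     seed=stage_seed(seed, "phylo"))
        except ValueError as err:
            log.warning("phylo stage skipped: %s", err)
        else:
            trees["nj"] = tree.newick
            tables["supports"] = pd.DataFrame(
                [{"split": "|".join(sorted(s)), "support": v}
                 for s, v in tree.support.items()], columns=["split", "support"])

    written = write_results(tables, trees, fastas, out)
    for name in written["file"]:
        manifest.record(out / name)
    manifest.write(out / "run_manifest.json")
    return manifest
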
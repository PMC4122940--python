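"""End-to-end orchestration of the synthetic-study workflow.

Stages: simulate -> duplication mapping -> methylation divergence ->
chromatin divergence -> lineage analyses -> annotation -> interaction
model.  Each stage writes its tables under the output directory and
contributes to a single JSON summary; thresholds default to the study
values (per-site depth >= 6, total depth <= 100, alpha 5e-7,
concordance delta 0.20, 100 permutations, 500-bp windows with 100-bp
offset, 2-kb shores/promoters, 0.4/0.6 remodeling thresholds, 1-kb
flank radius) and are all logged for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, chromdiv, diffmodel, dupmap, io, lineage, methdiv
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("paradiverge.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""


@dataclass
class PipelineConfig:
    bundle_dir: str = ""
    simulate_first: bool = True
    alpha: float = 5e-7
    delta: float = 0.20
    min_depth: int = 6
    max_total_depth: int = 100
    n_permutations: int = 100
    window: int = 500
    profile_offset: int = 100
    profile_max_dist: int = 2000
    shore_width: int = 2000
    low_threshold: float = 0.4
    min_gain: float = 0.6
    flank_radius: int = 1000
    promoter_window: int = 2000
    min_ortho_depth: int = 5
    seed: int = 0
    simulation: SimulationConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = d.pop("simulation", None)
        cfg = cls(**d)
        if sim is not None:
            sim = {k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()}
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc

        return inner

    return wrap


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and return (and write) the summary dictionary.

    With ``simulate_first`` the synthetic bundle is generated into
    ``out_dir/bundle`` using ``config.simulation`` (or defaults seeded
    from ``config.seed``); otherwise ``bundle_dir`` must point at an
    existing bundle laid out as by the simulator.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": {
        k: v for k, v in dataclasses.asdict(config).items() if k != "simulation"
    }}

    # --- simulate ---------------------------------------------------------
    if config.simulate_first:
        sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
        bundle = out / "bundle"
        _stage("simulate")(simulate_dataset)(sim_cfg, bundle)
    else:
        bundle = Path(config.bundle_dir)
    manifest_path = bundle / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError(f"stage inputs: missing manifest {manifest_path}")
    manifest = io.read_json(manifest_path)

    def bpath(key: str) -> Path:
        p = bundle / manifest[key]
        if not p.exists():
            raise PipelineError(f"stage inputs: missing file {p} (manifest key {key!r})")
        return p

    # --- duplication mapping ---------------------------------------------
    @_stage("dupmap")
    def _dupmap():
        genome = io.read_fasta(bpath("genome"))
        alignments = dupmap.parse_duplication_alignments(bpath("alignments"))
        pairings = dupmap.find_paralogous_cpg_pairs(alignments, genome)
        return genome, alignments, pairings

    genome, alignments, pairings = _dupmap()
    summary["n_alignments"] = len(alignments)
    summary["n_pairs_enumerated"] = len(pairings)

    # --- methylation divergence --------------------------------------------
    @_stage("methdiv")
    def _methdiv():
        coverage = io.coverage_dict(io.read_coverage(bpath("coverage_base")))
        flags = io.read_site_flags(bpath("site_flags"))
        snps = methdiv.IntervalSet.from_bed(io.read_bed(bpath("snps")))
        pairs = methdiv.attach_counts(pairings, coverage, flags)
        policy = methdiv.FilterPolicy(
            min_depth_per_site=config.min_depth,
            max_total_depth=config.max_total_depth,
            snp_intervals=snps,
        )
        retained, rejections = methdiv.filter_pairs(pairs, policy)
        for p in retained:
            methdiv.test_discordance(p)
        discordant = methdiv.classify_discordant(retained, alpha=config.alpha)
        conc = methdiv.concordance_summary(retained, delta=config.delta)
        perm = methdiv.permutation_null(
            retained, n_perm=config.n_permutations, delta=config.delta, seed=config.seed
        )
        loci = methdiv.dedupe_within_1kb(discordant)
        seqdiv = methdiv.sequence_divergence_association(retained, alignments)
        return pairs, retained, rejections, discordant, conc, perm, loci, seqdiv

    (pairs, retained, rejections, discordant, conc, perm, loci, seqdiv) = _methdiv()
    summary["pair_rejections"] = rejections
    summary["n_pairs_retained"] = len(retained)
    summary["concordance_proportion"] = _round(conc["proportion_within_delta"])
    summary["spearman_rho"] = _round(conc["spearman_rho"])
    summary["permutation_p"] = _round(perm["p_value"])
    summary["n_discordant"] = len(discordant)
    summary["n_discordant_loci"] = len(loci)
    summary["seqdiv_kruskal_p"] = _round(seqdiv["kruskal_p"])

    pair_table = pd.DataFrame(
        [
            {
                "chrom_a": p.site_a.chrom, "pos_a": p.site_a.pos,
                "chrom_b": p.site_b.chrom, "pos_b": p.site_b.pos,
                "meth_a": p.counts_a.methylated, "unmeth_a": p.counts_a.unmethylated,
                "meth_b": p.counts_b.methylated, "unmeth_b": p.counts_b.unmethylated,
                "level_a": round(p.level_a, 6), "level_b": round(p.level_b, 6),
                "p_value": p.p_value, "discordant": p.discordant,
                "hyper_copy": p.hyper or ".",
            }
            for p in retained
        ]
    )
    pair_table.to_csv(out / "pair_table.tsv", sep="\t", index=False)
    if discordant:
        disc_bed = pd.DataFrame(
            [
                (p.site_a.chrom, p.site_a.pos, p.site_a.pos + 2, "discordant_a", 0, "+")
                for p in discordant
            ]
            + [
                (p.site_b.chrom, p.site_b.pos, p.site_b.pos + 2, "discordant_b", 0, "+")
                for p in discordant
            ],
            columns=io.BED_COLUMNS,
        ).sort_values(["chrom", "start"], kind="mergesort")
        io.write_bed(disc_bed, out / "discordant_sites.bed")

    # --- ancestral / derived ------------------------------------------------
    @_stage("ancestral")
    def _ancestral():
        polarity = lineage.ChainMap(io.read_chain_file(bpath("polarity_chain")))
        synteny_df = pd.read_csv(bpath("synteny"), sep="\t")
        synteny = dict(zip(synteny_df["chrom"], synteny_df["outgroup_chrom"]))
        counts = {"a": 0, "b": 0, "undetermined": 0}
        assignments = {}
        for p in retained:
            if p.site_a.chrom == p.site_b.chrom:
                continue
            res = lineage.assign_ancestral_derived(p, polarity, synteny)
            counts[res] += 1
            assignments[p.key] = res
        return counts, assignments

    anc_counts, anc_assignments = _ancestral()
    summary["ancestral_assignments"] = anc_counts

    # --- chromatin divergence -------------------------------------------------
    @_stage("chromdiv")
    def _chromdiv():
        mappability = chromdiv.MappabilityTrack.from_bed(io.read_bed(bpath("mappability")))
        windows = []
        for idx, aln in enumerate(alignments):
            windows.extend(
                chromdiv.make_window_pairs(
                    aln, mappability, size=config.window, alignment_index=idx
                )
            )
        per_mark = {}
        flank_tests = {}
        for mark, rel in sorted(manifest["reads"].items()):
            reads = io.read_bed(bundle / rel)
            chromdiv.count_reads_in_windows(windows, reads)
            disc_windows = chromdiv.classify_discordant_windows(windows)
            per_mark[mark] = {
                "tested": sum(1 for w in windows if w.testable),
                "discordant": len(disc_windows),
            }
            win_table = pd.DataFrame(
                [
                    {
                        "chrom_a": w.chrom_a, "a_start": w.a_start, "a_end": w.a_end,
                        "chrom_b": w.chrom_b, "mask": w.mask_size,
                        "count_a": w.count_a, "count_b": w.count_b,
                        "p_value": w.p_value, "discordant": w.discordant,
                    }
                    for w in windows
                ]
            )
            win_table.to_csv(out / f"windows_{mark}.tsv", sep="\t", index=False)
            prof = chromdiv.flanking_read_profile(discordant, reads, flank=config.window)
            flank_tests[mark] = _round(prof["wilcoxon_p"])
        return per_mark, flank_tests

    per_mark, flank_tests = _chromdiv()
    summary["windows_per_mark"] = per_mark
    summary["flank_read_wilcoxon_p"] = flank_tests

    # --- lineage ---------------------------------------------------------------
    @_stage("lineage")
    def _lineage():
        map1 = lineage.ChainMap(io.read_chain_file(bpath("outgroup1_chain")))
        map2 = lineage.ChainMap(io.read_chain_file(bpath("outgroup2_chain")))
        repeats = io.read_bed(bpath("repeats"))
        events = lineage.detect_lineage_specific_insertions(
            repeats, map1, map2, families=("Alu",)
        )
        og_events = lineage.detect_outgroup_insertions(map1, map2)
        cov_h = io.coverage_dict(io.read_coverage(bpath("coverage_human_brain")))
        cov_o = io.coverage_dict(io.read_coverage(bpath("coverage_outgroup_brain")))
        ortho = lineage.match_orthologous_cpgs(
            cov_h, cov_o, map1, min_depth=config.min_ortho_depth
        )
        profile = lineage.flanking_methylation_profile(
            events, ortho, window=config.window,
            offset=config.profile_offset, max_dist=config.profile_max_dist,
        )
        profile.to_csv(out / "flanking_profile_human.tsv", sep="\t", index=False)
        t_res = lineage.paired_flank_test(events, ortho, radius=config.flank_radius)
        background, foreground = lineage.select_remodeled_sites(
            ortho, events,
            proximity=config.promoter_window,
            low_threshold=config.low_threshold, min_gain=config.min_gain,
        )
        for name, sites in (("background", background), ("foreground", foreground)):
            df = pd.DataFrame(
                [(s.chrom_x, s.pos_x, s.pos_x + 2, name, 0, "+") for s in sites],
                columns=io.BED_COLUMNS,
            )
            io.write_bed(df, out / f"remodeled_{name}.bed")
        genes = pd.read_csv(bpath("expression"), sep="\t")
        expr = lineage.expression_linkage(
            genes, foreground, promoter_window=config.promoter_window
        )
        return events, og_events, ortho, t_res, background, foreground, expr

    events, og_events, ortho, t_res, background, foreground, expr = _lineage()
    summary["n_insertions_human"] = len(events)
    summary["n_insertions_outgroup"] = len(og_events)
    summary["n_orthologous_cpgs"] = len(ortho)
    summary["paired_t_p"] = _round(t_res["p"], 10)
    summary["paired_t_stat"] = _round(t_res["t"], 4)
    summary["n_remodeled_background"] = len(background)
    summary["n_remodeled_foreground"] = len(foreground)
    summary["expression_linkage"] = {
        "lower": expr["lower"], "higher": expr["higher"], "tied": expr["tied"],
        "sign_test_p": _round(expr["sign_test_p"]),
    }

    # --- annotation --------------------------------------------------------------
    @_stage("annotate")
    def _annotate():
        islands = annotate.FeatureTrack(io.read_bed(bpath("cpg_islands")), "islands")
        tss = annotate.FeatureTrack(io.read_bed(bpath("tss")), "tss")
        repeats_track = annotate.FeatureTrack(io.read_bed(bpath("repeats")), "repeats")
        disc_a_sites = [p.site_a for p in discordant]
        classes = annotate.classify_island_shore(
            disc_a_sites or [p.site_a for p in retained], islands,
            shore_width=config.shore_width,
        )
        class_counts = {c: classes.count(c) for c in ("island", "shore", "open_sea")}
        tss_table = annotate.tss_distance_table(retained, tss)
        tss_table.to_csv(out / "tss_distances.tsv", sep="\t", index=False)
        frac_distal = annotate.fraction_distal(tss_table)
        rep = annotate.repeat_proximity_test(discordant, repeats_track)
        conc_sites = [p.site_a for p in retained if not p.discordant]
        junction = annotate.junction_distance_test(
            disc_a_sites, conc_sites, [a.copy_a for a in alignments] + [a.copy_b for a in alignments]
        )
        hyper_sites = [
            (p.site_a if p.hyper == "a" else p.site_b) for p in discordant
        ]
        hypo_sites = [
            (p.site_b if p.hyper == "a" else p.site_a) for p in discordant
        ]
        deduped = methdiv.dedupe_within_1kb(discordant)
        annotate.export_flank_fasta(
            {"hyper": hyper_sites, "hypo": hypo_sites}, genome, out / "motif_input"
        )
        return class_counts, frac_distal, rep, junction, deduped

    class_counts, frac_distal, rep, junction, deduped = _annotate()
    summary["discordant_site_classes"] = class_counts
    summary["tss_fraction_distal"] = _round(frac_distal)
    summary["repeat_proximity_p"] = {k: _round(v["p"]) for k, v in rep.items()}
    summary["junction_distance"] = {
        "median_discordant": junction["median_discordant"],
        "median_concordant": junction["median_concordant"],
        "p": _round(junction["p"]),
    }

    # --- interaction model ----------------------------------------------------------
    @_stage("model")
    def _model():
        cov_base = io.coverage_dict(io.read_coverage(bpath("coverage_base")))
        cov_diff = io.coverage_dict(io.read_coverage(bpath("coverage_diff")))
        rows = []
        for p in retained:
            ka = (p.site_a.chrom, p.site_a.pos)
            base = cov_base.get(ka)
            diff = cov_diff.get(ka)
            if not base or not diff:
                continue
            if base[0] + base[1] < config.min_depth or diff[0] + diff[1] < config.min_depth:
                continue
            x1 = base[0] / (base[0] + base[1])
            x2 = diff[0] / (diff[0] + diff[1]) - x1
            rows.append({"x1": x1, "x2": x2, "y": p.abs_difference})
        data = pd.DataFrame(rows)
        fit = diffmodel.fit_interaction_model(data)
        binned = diffmodel.binned_divergence_summary(data)
        binned.to_csv(out / "binned_divergence.tsv", sep="\t", index=False)
        data.to_csv(out / "model_input.tsv", sep="\t", index=False)
        return fit

    fit = _model()
    summary["model"] = {
        "coefficients": [_round(c) for c in fit.coefficients],
        "r_squared": _round(fit.r_squared),
        "n": fit.nobs,
        "p_values": {k: _round(v, 10) for k, v in fit.pvalues.items()},
    }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", out / "summary.json")
    return summary
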
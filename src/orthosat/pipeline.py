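"""End-to-end orchestration of the commensurability pipeline.

Stages, in order: in-silico PCR against each species' reference
(amplicon identification decision tree), STR detection within the chosen
fragments, interspecies range/criterion assessment, STR-anchored flank
alignment, structure-concordance classification, fragment-length to
repeat-number calibration, and population-genetic statistics on both genotype
representations, including the length-vs-repeat inflation summary.

Every input marker receives exactly one fate in the disposition ledger
(retained plus each rejection class sum to the input total), and all
randomness flows from the single config seed.  Logging goes to stderr;
results never do.
"""
from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import assess as osassess
from . import calibrate as oscal
from . import epcr as osepcr
from . import flankalign as osalign
from . import io as osio
from . import popgen as ospop
from . import strdetect as osstr
from .types import GenotypeDataset, LengthRange, PopulationDistance, PrimerPair

logger = logging.getLogger("orthosat")

EXIT_OK = 0
EXIT_INPUT_ERROR = 2
EXIT_STAGE_FAILURE = 3

FATE_RETAINED = "retained_popgen"
FATE_EPCR = "epcr_{outcome}"
FATE_NO_HUMAN = "excluded_no_human_fragment"
FATE_DISJOINT = "excluded_disjoint_ranges"
FATE_CRITERIA = "excluded_length_criteria"
FATE_STRUCTURE = "excluded_structure_{concordance}"
FATE_MIXED_UNIT = "excluded_mixed_unit"
FATE_NO_STR = "excluded_no_str"


@dataclass
class RunConfig:
    chimp_fasta: str = ""
    human_fasta: str = ""
    primers: str = ""
    genotypes: str = ""
    samples: str = ""
    out_dir: str = "orthosat_out"
    min_repeats: int = 4
    slack_bp: int = osepcr.DEFAULT_SLACK_BP
    ros_threshold: float = osassess.DEFAULT_ROS_THRESHOLD
    derive_threshold: bool = False
    min_pop_size: int = 5
    resample_sets: int = 1000
    resample_size: int = 84
    seed: int = 0
    genotype_dialect: str = "long"
    run_popgen: bool = True
    run_profile: bool = False


@dataclass
class RunResult:
    disposition: pd.DataFrame
    epcr_decisions: dict
    assessments: list
    concordances: dict
    alignments: dict
    models: dict
    repeats_dataset: GenotypeDataset | None
    normalization_report: dict
    fst_length: ospop.PairwiseMatrix | None = None
    fst_repeats: ospop.PairwiseMatrix | None = None
    dps_length: ospop.PairwiseMatrix | None = None
    dps_repeats: ospop.PairwiseMatrix | None = None
    fst_inflation: ospop.InflationReport | None = None
    dps_inflation: ospop.InflationReport | None = None
    profiles: pd.DataFrame | None = None


def _stage(name):
    logger.info("stage %s", name)
    return time.time()


def run_all(primer_pairs: list[PrimerPair],
            chimp_refs: dict[str, str], human_refs: dict[str, str],
            genotypes: GenotypeDataset,
            distances: dict[str, PopulationDistance] | None = None,
            config: RunConfig | None = None,
            out_dir: str | Path | None = None) -> RunResult:
    """Run every stage on in-memory inputs; optionally write reports to out_dir."""
    cfg = config or RunConfig()
    fates: dict[str, str] = {}
    epcr_decisions: dict[str, dict] = {}
    structures: dict[str, dict] = {}
    fragments: dict[str, dict] = {}
    assessments = []
    concordances: dict[str, osstr.StructureConcordance] = {}
    alignments: dict[str, osalign.OrthologAlignment] = {}
    models: dict[tuple, oscal.CalibrationModel] = {}

    markers = [p.marker_name for p in primer_pairs]
    by_marker = {p.marker_name: p for p in primer_pairs}

    t0 = _stage("epcr")
    for marker in markers:
        pp = by_marker[marker]
        epcr_decisions[marker] = {}
        failed = None
        for sp, refs in (("chimpanzee", chimp_refs), ("human", human_refs)):
            ref = refs.get(marker)
            observed = (genotypes.species_range(marker, sp)
                        if marker in genotypes.loci else None)
            if ref is None:
                decision = osepcr.EPCRDecision(marker, osepcr.OUTCOME_REJECTED_NO_HIT,
                                               None, 0)
            else:
                decision = osepcr.run_epcr(pp, ref, observed, species=sp,
                                           slack=cfg.slack_bp)
            epcr_decisions[marker][sp] = decision
            if decision.chosen_fragment is None and failed is None:
                failed = (sp, decision.outcome)
        if failed:
            sp, outcome = failed
            fates[marker] = (FATE_NO_HUMAN if sp == "human"
                             and outcome == osepcr.OUTCOME_REJECTED_NO_HIT
                             else FATE_EPCR.format(outcome=outcome))
        else:
            fragments[marker] = {sp: epcr_decisions[marker][sp].chosen_fragment
                                 for sp in ("chimpanzee", "human")}
    logger.info("epcr done in %.2fs", time.time() - t0)

    t0 = _stage("detect-str")
    for marker, frags in fragments.items():
        structures[marker] = {}
        for sp, frag in frags.items():
            s = osstr.find_str_regions(frag.sequence, min_repeats=cfg.min_repeats)
            structures[marker][sp] = osstr.harmonize_boundaries(s, frag.sequence)
    logger.info("detect-str done in %.2fs", time.time() - t0)

    t0 = _stage("assess")
    surviving = []
    for marker in list(fragments):
        c_range = genotypes.species_range(marker, "chimpanzee")
        h_range = genotypes.species_range(marker, "human")
        if c_range is None or h_range is None:
            fates[marker] = FATE_CRITERIA
            continue
        a = osassess.assess_lengths(
            marker,
            fragments[marker]["chimpanzee"].adjusted_length,
            fragments[marker]["human"].adjusted_length,
            c_range, h_range,
            ros_threshold=cfg.ros_threshold, slack=cfg.slack_bp)
        assessments.append(a)
        if not a.retained:
            fates[marker] = (FATE_DISJOINT
                             if a.range_class == osassess.RANGE_DISJOINT
                             else FATE_CRITERIA)
        else:
            surviving.append(marker)
    logger.info("assess done in %.2fs", time.time() - t0)

    t0 = _stage("align + concordance")
    calib_markers = []
    for marker in surviving:
        cs = fragments[marker]["chimpanzee"].sequence
        hs = fragments[marker]["human"].sequence
        aln = osalign.align_orthologs(cs, hs,
                                      structures[marker]["chimpanzee"],
                                      structures[marker]["human"], marker)
        alignments[marker] = aln
        conc = osstr.compare_structures(structures[marker]["chimpanzee"],
                                        structures[marker]["human"], cs, hs, aln)
        concordances[marker] = conc
        if conc.concordance != osstr.IDENTICAL:
            fates[marker] = FATE_STRUCTURE.format(concordance=conc.concordance)
            continue
        calib_markers.append(marker)
    logger.info("align done in %.2fs", time.time() - t0)

    t0 = _stage("calibrate")
    retained = []
    for marker in calib_markers:
        try:
            for sp in ("chimpanzee", "human"):
                models[(marker, sp)] = oscal.build_model(fragments[marker][sp],
                                                         structures[marker][sp])
        except oscal.MixedUnitError:
            fates[marker] = FATE_MIXED_UNIT
            models = {k: v for k, v in models.items() if k[0] != marker}
            continue
        except ValueError:
            fates[marker] = FATE_NO_STR
            continue
        fates[marker] = FATE_RETAINED
        retained.append(marker)
    logger.info("calibrate done in %.2fs", time.time() - t0)

    repeats_ds = None
    norm_report: dict = {}
    result = RunResult(disposition=None, epcr_decisions=epcr_decisions,
                       assessments=assessments, concordances=concordances,
                       alignments=alignments, models=models,
                       repeats_dataset=None, normalization_report={})
    if retained and cfg.run_popgen:
        t0 = _stage("popgen")
        lengths_sub = genotypes.subset_loci(retained)
        repeats_ds, norm_report = oscal.normalize_dataset(lengths_sub, models)
        result.repeats_dataset = repeats_ds
        result.normalization_report = norm_report
        try:
            result.fst_length = ospop.pairwise_fst(lengths_sub, cfg.min_pop_size)
            result.fst_repeats = ospop.pairwise_fst(repeats_ds, cfg.min_pop_size)
            result.dps_length = ospop.pairwise_dps(lengths_sub, cfg.min_pop_size)
            result.dps_repeats = ospop.pairwise_dps(repeats_ds, cfg.min_pop_size)
            result.fst_inflation = ospop.inflation_summary(
                result.fst_length, result.fst_repeats, distances)
            result.dps_inflation = ospop.inflation_summary(
                result.dps_length, result.dps_repeats, distances)
        except ValueError as exc:
            logger.warning("popgen stage skipped: %s", exc)
        if cfg.run_profile:
            result.profiles = ospop.variability_profile(
                repeats_ds, lengths_sub, cfg.resample_sets, cfg.resample_size,
                seed=cfg.seed)
        logger.info("popgen done in %.2fs", time.time() - t0)

    rows = [{"marker": m, "fate": fates[m]} for m in markers]
    disposition = pd.DataFrame(rows)
    assert set(disposition["marker"]) == set(markers)
    result.disposition = disposition

    if out_dir is not None:
        _write_reports(result, cfg, Path(out_dir))
    return result


def _matrix_tsv(m: ospop.PairwiseMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# orthosat {m.statistic} matrix representation={m.representation}\n")
        fh.write("population\t" + "\t".join(m.populations) + "\n")
        for i, p in enumerate(m.populations):
            fh.write(p + "\t" + "\t".join(f"{v:.6f}" for v in m.values[i]) + "\n")


def _write_reports(result: RunResult, cfg: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.disposition.to_csv(out_dir / "disposition.tsv", sep="\t", index=False)

    rows = []
    for marker, per_sp in result.epcr_decisions.items():
        for sp, d in per_sp.items():
            frag = d.chosen_fragment
            rows.append({
                "marker": marker, "species": sp, "outcome": d.outcome,
                "candidates": d.candidates_considered,
                "raw_len": frag.raw_length if frag else "",
                "adjusted_len": frag.adjusted_length if frag else "",
                "margin_bp": d.margin_bp if d.margin_bp is not None else ""})
    pd.DataFrame(rows).to_csv(out_dir / "epcr.tsv", sep="\t", index=False)

    pd.DataFrame([{
        "marker": a.marker, "range_class": a.range_class, "criterion": a.criterion,
        "ros": "" if a.ros is None else f"{a.ros:.4f}",
        "retained": a.retained, "reason": a.reason}
        for a in result.assessments]).to_csv(out_dir / "assess.tsv", sep="\t",
                                             index=False)

    rows = []
    for marker, aln in result.alignments.items():
        c_only, h_only = aln.species_specific_counts()
        conc = result.concordances.get(marker)
        rows.append({"marker": marker, "anchored": aln.anchored,
                     "chimp_only_nonstr_nt": c_only, "human_only_nonstr_nt": h_only,
                     "concordance": conc.concordance if conc else "",
                     "affected": conc.affected_species if conc else ""})
    pd.DataFrame(rows).to_csv(out_dir / "alignments.tsv", sep="\t", index=False)

    pd.DataFrame([{
        "marker": m.marker, "species": m.species,
        "ref_len": m.ref_adjusted_length, "ref_repeats": m.ref_total_repeats,
        "unit": m.unit_size}
        for m in result.models.values()]).to_csv(out_dir / "models.tsv", sep="\t",
                                                 index=False)

    if result.repeats_dataset is not None:
        osio.write_genotypes(result.repeats_dataset, out_dir / "genotypes_repeats.tsv")
    for name, m in (("fst_length", result.fst_length),
                    ("fst_repeats", result.fst_repeats),
                    ("dps_length", result.dps_length),
                    ("dps_repeats", result.dps_repeats)):
        if m is not None:
            _matrix_tsv(m, out_dir / f"{name}.tsv")
    for name, rep in (("fst", result.fst_inflation), ("dps", result.dps_inflation)):
        if rep is not None:
            rep.per_pair.to_csv(out_dir / f"inflation_{name}_pairs.tsv", sep="\t",
                                index=False)
    if result.profiles is not None:
        result.profiles.to_csv(out_dir / "profiles.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "min_repeats": cfg.min_repeats, "slack_bp": cfg.slack_bp,
            "ros_threshold": cfg.ros_threshold, "min_pop_size": cfg.min_pop_size,
            "resample": f"{cfg.resample_sets}x{cfg.resample_size}"},
        "normalization": result.normalization_report,
        "summary": {
            "markers": int(len(result.disposition)),
            "retained": int((result.disposition["fate"] == FATE_RETAINED).sum())},
    }
    if result.fst_inflation is not None:
        manifest["fst_inflation"] = {
            "max_pct": result.fst_inflation.max_reduction_pct,
            "mean_pct": result.fst_inflation.mean_reduction_pct,
            "sd_pct": result.fst_inflation.sd_reduction_pct,
            "r_squared": result.fst_inflation.r_squared}
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)


def run_all_from_files(config: RunConfig) -> RunResult:
    """Load every input from the paths in config and run the pipeline."""
    try:
        primer_pairs = osio.read_primer_table(config.primers)
        chimp_raw = osio.read_fasta(config.chimp_fasta)
        human_raw = osio.read_fasta(config.human_fasta)
        genotypes = osio.read_genotypes(config.genotypes, config.samples,
                                        dialect=config.genotype_dialect)
        _, _, _, distances = osio.read_samples(config.samples)
    except (OSError, ValueError, KeyError) as exc:
        logger.error("input error: %s", exc)
        raise SystemExit(EXIT_INPUT_ERROR) from exc

    def strip(records):
        return {osio.split_fasta_id(k)[0]: v for k, v in records.items()}

    return run_all(primer_pairs, strip(chimp_raw), strip(human_raw), genotypes,
                   distances or None, config, out_dir=config.out_dir)
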
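"""Shared fixtures: synthetic studies and pipeline runs are built once per session."""
from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

import orthosat as o  # noqa: E402

STUDY_SEED = 3
MIMIC_SEED = 7

# one marker per decision-tree branch / structure-concordance class
EXPECTED_FATES = {
    "M_RET": "retained_popgen",
    "M_PIG": "retained_popgen",
    "M_ADE": "retained_popgen",
    "M_NOHIT": "epcr_rejected_no_hit",
    "M_FAR": "epcr_rejected_length",
    "M_OVL": "retained_popgen",
    "M_MULTI": "epcr_rejected_multi_hit",
    "M_IDENT": "retained_popgen",
    "M_CSUB": "retained_popgen",
    "M_HSUB": "retained_popgen",
    "M_PLOW": "retained_popgen",
    "M_PHIGH": "retained_popgen",
    "M_DISJ": "excluded_disjoint_ranges",
    "M_CRIT2": "retained_popgen",
    "M_CRIT3": "retained_popgen",
    "M_FAIL3": "excluded_length_criteria",
    "M_3REP": "excluded_structure_three_repeat_variant",
    "M_2REP": "excluded_structure_two_repeat_variant",
    "M_DISR": "excluded_structure_disrupted_variant",
    "M_NOSTR": "excluded_structure_no_str",
    "M_MIXED": "excluded_mixed_unit",
    "M_INDEL": "retained_popgen",
}


@pytest.fixture(scope="session")
def study():
    """Default branch-coverage study."""
    return o.make_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def pipeline_result(study):
    return o.run_all(study.primer_pairs, study.reference_records("chimpanzee"),
                     study.reference_records("human"), study.genotypes,
                     study.distances, o.RunConfig(seed=STUDY_SEED), None)


@pytest.fixture(scope="session")
def mimic_study():
    """Study-mimicking concordant panel with planted flank indels at half the loci."""
    cfgs = o.concordant_panel_configs(n_loci=24, indel_fraction=0.5, seed=MIMIC_SEED)
    return o.make_study(cfgs, seed=MIMIC_SEED)


@pytest.fixture(scope="session")
def zero_indel_study():
    """Same construction with no planted indels: lengths commensurable by design."""
    cfgs = o.concordant_panel_configs(n_loci=12, indel_fraction=0.0, seed=MIMIC_SEED)
    return o.make_study(cfgs, seed=MIMIC_SEED)
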
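"""Simulator: determinism, mixture/X-dosage structure, error processes."""

import numpy as np
import pytest

from ampmeth.errors import ValidationError
from ampmeth.panel import PanelConfig
from ampmeth.pipeline import call_reads
from ampmeth.quantify import treg_like_fraction
from ampmeth.simulate import (
    SampleDesign,
    SimDesign,
    build_sample_sheet,
    naive_profile,
    simulate,
    synthetic_panel,
    titration_design,
    treg_profile,
    truth_demethylated_fraction,
    write_fastq,
)


def _single_sample_design(panel, p_treg, sex="male", reads=500, seed=0, **rates):
    sample = SampleDesign(
        sample_id="S1", mixture={"treg": p_treg, "naive": 1.0 - p_treg}, sex=sex
    )
    sheet = build_sample_sheet([sample], seed=seed)
    return SimDesign(
        panel=panel,
        sample_sheet=sheet,
        profiles=(treg_profile(panel), naive_profile(panel)),
        samples=(sample,),
        reads_per_replicate=reads,
        seed=seed,
        **rates,
    )


@pytest.fixture(scope="module")
def foxp3_panel():
    return PanelConfig((synthetic_panel().amplicons[0],), version="test")


def test_deterministic_rerun_byte_identical(tmp_path, foxp3_panel):
    design = _single_sample_design(foxp3_panel, 0.5, reads=200, seed=123)
    rec1, truth1 = simulate(design)
    rec2, truth2 = simulate(design)
    assert rec1 == rec2
    assert truth1.equals(truth2)
    p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
    write_fastq(rec1, p1)
    write_fastq(rec2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_pure_treg_male_perfect_chemistry_reads_all_u(foxp3_panel):
    design = _single_sample_design(
        foxp3_panel, 1.0, reads=200, conversion_rate=1.0, seq_error_rate=0.0
    )
    records, truth = simulate(design)
    calls, _, _ = call_reads(iter(records), design.sample_sheet, design.panel)
    n = foxp3_panel.amplicons[0].n_included
    assert all(c.passed and c.pattern == "U" * n for c in calls)
    assert truth_demethylated_fraction(truth)["S1"] == 1.0


def test_female_x_dosage_halves_demethylated_fraction(foxp3_panel):
    """Half of female template molecules are the methylated inactive-X copy,
    so a pure Treg female sample reads ~50% fully demethylated."""
    reads = 2000
    design = _single_sample_design(
        foxp3_panel, 1.0, sex="female", reads=reads,
        conversion_rate=1.0, seq_error_rate=0.0, seed=21,
    )
    records, truth = simulate(design)
    calls, _, _ = call_reads(iter(records), design.sample_sheet, design.panel)
    n = foxp3_panel.amplicons[0].n_included
    frac_u = np.mean([c.pattern == "U" * n for c in calls if c.passed])
    se = np.sqrt(0.25 / reads)
    assert abs(frac_u - 0.5) <= 3 * se
    assert abs(truth_demethylated_fraction(truth)["S1"] - 0.5) <= 3 * se


def test_per_site_miscall_bounded_by_error_rate(foxp3_panel):
    """Substitution errors produce N (or a flip) at most at the per-base
    error rate; with perfect conversion the U-rate on an all-methylated
    profile stays below epsilon per site."""
    eps = 0.01
    design = _single_sample_design(
        foxp3_panel, 0.0, reads=3000, conversion_rate=1.0, seq_error_rate=eps, seed=4
    )
    records, _ = simulate(design)
    calls, _, _ = call_reads(iter(records), design.sample_sheet, design.panel)
    n = foxp3_panel.amplicons[0].n_included
    per_site_u = np.zeros(n)
    usable = [c for c in calls if c.pattern]
    for c in usable:
        per_site_u += np.array([ch == "U" for ch in c.pattern])
    per_site_u /= len(usable)
    # C->T is one of three substitution outcomes, so the miscall rate per
    # site is ~eps/3; allow binomial noise up to eps itself
    assert per_site_u.max() <= eps


def test_error_floor_far_below_two_percent(foxp3_panel):
    """A fully methylated sample needs >= n-1 independent failures on one
    read to look Treg-like, so the artefact rate is essentially zero."""
    design = _single_sample_design(
        foxp3_panel, 0.0, reads=3000, conversion_rate=0.995, seq_error_rate=0.001, seed=6
    )
    records, _ = simulate(design)
    calls, _, _ = call_reads(iter(records), design.sample_sheet, design.panel)
    frac = treg_like_fraction([c for c in calls if c.passed], min_k=8)
    assert frac < 2.0


def test_end_to_end_mixture_recovery_unbiased(foxp3_panel):
    """Pipeline estimate of the demethylated fraction tracks simulated truth
    within 3 binomial SE across seeds."""
    p = 0.3
    reads = 1500
    for seed in (1, 2, 3):
        design = _single_sample_design(
            foxp3_panel, p, reads=reads, conversion_rate=0.995,
            seq_error_rate=0.001, seed=seed,
        )
        records, truth = simulate(design)
        calls, _, _ = call_reads(iter(records), design.sample_sheet, design.panel)
        est = treg_like_fraction([c for c in calls if c.passed], min_k=8) / 100
        true_frac = truth_demethylated_fraction(truth)["S1"]
        se = np.sqrt(p * (1 - p) / reads)
        assert abs(est - true_frac) <= 3 * se


def test_titration_design_wrapper(foxp3_panel):
    p_values = [0, 0.2, 0.4, 0.6, 0.8, 1.0]
    designs = titration_design(p_values, reads_per_point=50, seed=9, panel=foxp3_panel)
    assert len(designs) == 6
    _, truth0 = simulate(designs[0])
    assert truth_demethylated_fraction(truth0).iloc[0] == 0.0
    _, truth1 = simulate(designs[-1])
    assert truth_demethylated_fraction(truth1).iloc[0] == 1.0


def test_design_validation():
    panel = PanelConfig((synthetic_panel().amplicons[0],))
    with pytest.raises(ValidationError):
        SampleDesign(sample_id="S", mixture={"treg": 0.6, "naive": 0.6})
    sample = SampleDesign(sample_id="S1", mixture={"ghost": 1.0})
    sheet = build_sample_sheet([sample], seed=0)
    with pytest.raises(ValidationError):
        SimDesign(
            panel=panel, sample_sheet=sheet,
            profiles=(treg_profile(panel),), samples=(sample,),
        )
    good = SampleDesign(sample_id="S1", mixture={"treg": 1.0})
    with pytest.raises(ValidationError):
        SimDesign(
            panel=panel, sample_sheet=build_sample_sheet([good], seed=0),
            profiles=(treg_profile(panel),), samples=(good,),
            conversion_rate=1.5,
        )


def test_truth_ids_match_fastq(foxp3_panel):
    design = _single_sample_design(foxp3_panel, 0.5, reads=100)
    records, truth = simulate(design)
    assert [r[0] for r in records] == truth["read_id"].tolist()
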
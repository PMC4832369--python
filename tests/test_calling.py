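"""Pattern caller: amplicon assignment, per-site calls, conversion QC."""

import itertools

import numpy as np
import pytest

from ampmeth.calling import (
    LOW_IDENTITY,
    TOO_MANY_N,
    TOO_SHORT,
    MethylationCall,
    assign_amplicon,
    call_pattern,
    conversion_efficiency,
)
from ampmeth.panel import PanelConfig, bisulfite_convert, expected_read, reverse_complement


def _trim(amp, full_read):
    return full_read[len(amp.forward_primer):]


def _oracle_call(seq, amp):
    """Independent position-by-position re-derivation of the pattern."""
    offset = amp.interior_start
    out = []
    for site in amp.included_sites:
        i = site.position - offset
        base = seq[i] if 0 <= i < len(seq) else "N"
        out.append("M" if base == "C" else "U" if base == "T" else "N")
    return "".join(out)


def test_assign_amplicon_exact(panel):
    for amp in panel:
        read = expected_read(amp, "M" * len(amp.cpg_sites))
        hit = assign_amplicon(read, panel)
        assert hit is not None and hit[0].name == amp.name and hit[1] == "+"


def test_assign_amplicon_unmatched(panel):
    assert assign_amplicon("G" * 60, panel, max_primer_mismatch=2) is None


def test_assign_amplicon_reverse_complement_orientation(foxp3, panel):
    read = expected_read(foxp3, "U" * len(foxp3.cpg_sites))
    rc = reverse_complement(read)
    # brute force over both orientations agrees
    hit = assign_amplicon(rc, panel)
    assert hit is not None and hit[0].name == foxp3.name and hit[1] == "-"


def test_assign_amplicon_tolerates_primer_mismatches(foxp3, panel):
    read = expected_read(foxp3, "M" * 10)
    mutated = "GG" + read[2:]  # 2 substitutions inside the primer
    hit = assign_amplicon(mutated, panel, max_primer_mismatch=2)
    assert hit is not None and hit[0].name == foxp3.name
    assert assign_amplicon(mutated, panel, max_primer_mismatch=1) is None


def test_call_pattern_tiny_examples(tiny_amplicon):
    call = call_pattern(expected_read(tiny_amplicon, "UU"), tiny_amplicon)
    assert call.pattern == "UU" and call.k_demethylated == 2 and call.passed

    call = call_pattern("ACGTTG", tiny_amplicon)
    assert call.pattern == "MU" and call.k_demethylated == 1


def test_call_pattern_n_at_site(tiny_amplicon):
    call = call_pattern("AGGTTG", tiny_amplicon)  # G at site position 1
    assert call.pattern == "NU"
    assert not call.passed and call.fail_reason == TOO_MANY_N
    relaxed = call_pattern("AGGTTG", tiny_amplicon, max_n=1)
    assert relaxed.passed


def test_call_pattern_too_short(foxp3):
    read = expected_read(foxp3, "U" * 10)
    stub = _trim(foxp3, read)[:20]  # ends before the last included CpG
    call = call_pattern(stub, foxp3)
    assert not call.passed and call.fail_reason == TOO_SHORT and call.pattern == ""


def test_call_pattern_low_identity(foxp3):
    read = _trim(foxp3, expected_read(foxp3, "M" * 10))
    garbled = "".join("A" if i % 2 else b for i, b in enumerate(read))
    call = call_pattern(garbled, foxp3, min_identity=0.90)
    assert not call.passed and call.fail_reason == LOW_IDENTITY


@pytest.mark.parametrize("n_exhaustive", [2])
def test_round_trip_exhaustive_tiny(tiny_amplicon, n_exhaustive):
    """Every pattern survives an error-free encode/decode round trip."""
    for bits in itertools.product("MU", repeat=n_exhaustive):
        pattern = "".join(bits)
        call = call_pattern(expected_read(tiny_amplicon, pattern), tiny_amplicon)
        assert call.pattern == pattern
        assert call.passed and call.identity_frac == 1.0
        assert call.noncpg_c_unconverted == 0


def test_round_trip_exhaustive_with_excluded_site(foxp3):
    """Excluded sites are encoded but dropped from the called pattern."""
    included_mask = [s.included for s in foxp3.cpg_sites]
    rng = np.random.default_rng(5)
    patterns = {"M" * 10, "U" * 10} | {
        "".join(rng.choice(["M", "U"], size=10)) for _ in range(40)
    }
    for pattern in sorted(patterns):
        read = _trim(foxp3, expected_read(foxp3, pattern))
        call = call_pattern(read, foxp3)
        expected = "".join(c for c, inc in zip(pattern, included_mask) if inc)
        assert call.pattern == expected
        assert call.pattern == _oracle_call(read, foxp3)
        assert call.k_demethylated == expected.count("U")
        assert call.passed


def test_caller_matches_oracle_on_noisy_reads(foxp3):
    rng = np.random.default_rng(9)
    base = _trim(foxp3, expected_read(foxp3, "M" * 10))
    for _ in range(50):
        chars = list(base)
        for i in rng.integers(0, len(chars), size=3):
            chars[i] = "ACGT"[rng.integers(0, 4)]
        noisy = "".join(chars)
        assert call_pattern(noisy, foxp3, min_identity=0.0, max_n=10).pattern == _oracle_call(
            noisy, foxp3
        )


def test_unconverted_noncpg_counted(foxp3):
    read = list(_trim(foxp3, expected_read(foxp3, "M" * 10)))
    offset = foxp3.interior_start
    # put back two unconverted cytosines at non-CpG positions
    for p in foxp3.noncpg_c_positions[:2]:
        read[p - offset] = "C"
    call = call_pattern("".join(read), foxp3)
    assert call.noncpg_c_unconverted == 2
    assert call.noncpg_c_total == len(foxp3.noncpg_c_positions)


def test_conversion_efficiency_arithmetic():
    calls = [
        MethylationCall(
            read_id=f"r{i}", amplicon="a", pattern="M", k_demethylated=0,
            noncpg_c_total=100, noncpg_c_unconverted=1, identity_frac=1.0, passed=True,
        )
        for i in range(10)
    ]
    qc = conversion_efficiency(calls)
    assert qc.efficiency == pytest.approx(99.0)
    assert qc.observations == 1000 and qc.unconverted == 10

    perfect = [
        MethylationCall(
            read_id="p", amplicon="a", pattern="M", k_demethylated=0,
            noncpg_c_total=50, noncpg_c_unconverted=0, identity_frac=1.0, passed=True,
        )
    ]
    assert conversion_efficiency(perfect).efficiency == pytest.approx(100.0)


def test_conversion_efficiency_ignores_failed_reads():
    calls = [
        MethylationCall(
            read_id="ok", amplicon="a", pattern="M", k_demethylated=0,
            noncpg_c_total=10, noncpg_c_unconverted=0, identity_frac=1.0, passed=True,
        ),
        MethylationCall(
            read_id="bad", amplicon="a", pattern="M", k_demethylated=0,
            noncpg_c_total=10, noncpg_c_unconverted=10, identity_frac=0.1,
            passed=False, fail_reason=LOW_IDENTITY,
        ),
    ]
    assert conversion_efficiency(calls).efficiency == pytest.approx(100.0)


def test_conversion_efficiency_zero_denominator_warns():
    with pytest.warns(UserWarning):
        qc = conversion_efficiency([])
    assert qc.efficiency is None


def test_conversion_efficiency_recovers_simulated_rate(foxp3):
    """Binomial sampling at success rate 0.995 lands within 3 SE of 99.5%."""
    rate = 0.995
    rng = np.random.default_rng(17)
    base = list(expected_read(foxp3, "M" * 10))
    offset = foxp3.interior_start
    calls = []
    n_obs = 0
    while n_obs < 10000:
        chars = base.copy()
        for p in foxp3.noncpg_c_positions:
            if rng.random() >= rate:
                chars[p] = "C"
        calls.append(call_pattern("".join(chars)[offset:], foxp3, min_identity=0.5))
        n_obs += len(foxp3.noncpg_c_positions)
    qc = conversion_efficiency(calls)
    se = 100 * np.sqrt(rate * (1 - rate) / qc.observations)
    assert qc.observations >= 10000
    assert abs(qc.efficiency - 99.5) <= 3 * se
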
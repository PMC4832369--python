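"""Per-read methylation pattern calling and bisulfite-conversion QC.

After demultiplexing, each read is assigned to an amplicon by matching
its 5' end against the panel's forward primers (trying the reverse
complement when no forward-orientation primer fits), then placed against
the amplicon by ungapped anchoring at the primer. Amplicons are short and
of fixed length, so no gapped aligner is used; reads whose non-CpG
identity to the converted reference falls below ``min_identity`` are
treated as indel-bearing or chimeric and fail.

At each included CpG the read base is interpreted as C -> M (methylated),
T -> U (demethylated), anything else -> N (no call). Non-CpG reference
cytosines can never be methylated, so an unconverted C observed there
measures bisulfite failure; their aggregate gives the conversion
efficiency reported per sample x amplicon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

from ampmeth.panel import AmpliconDef, PanelConfig, reverse_complement
from ampmeth.demux import hamming

UNMATCHED = "UNMATCHED"

# fail reasons
TOO_SHORT = "TOO_SHORT"
LOW_IDENTITY = "LOW_IDENTITY"
TOO_MANY_N = "TOO_MANY_N"


@dataclass
class MethylationCall:
    """One read's epiallele call plus the QC evidence behind it.

    ``pattern`` is a string over {M, U, N}, one character per *included*
    CpG site in position order. ``k_demethylated`` counts U characters.
    ``identity_frac`` is the fraction of aligned non-CpG, non-primer
    positions matching the converted reference.
    """

    read_id: str
    amplicon: str
    pattern: str
    k_demethylated: int
    noncpg_c_total: int
    noncpg_c_unconverted: int
    identity_frac: float
    passed: bool
    fail_reason: str = ""
    sample_id: str = ""
    replicate_id: str = ""
    orientation: str = "+"

    def __post_init__(self) -> None:
        assert self.k_demethylated == self.pattern.count("U")
        assert 0 <= self.noncpg_c_unconverted <= self.noncpg_c_total
        assert 0.0 <= self.identity_frac <= 1.0

    @property
    def n_count(self) -> int:
        return self.pattern.count("N")


@dataclass
class ConversionQC:
    """Bisulfite conversion efficiency over the passed reads of one stratum.

    ``efficiency`` is ``100 * converted / (converted + unconverted)``
    over non-CpG cytosine observations; ``None`` when no observation was
    available (reported as missing, with a warning).
    """

    amplicon: str = ""
    sample: str = ""
    efficiency: Optional[float] = None
    observations: int = 0
    unconverted: int = 0


def assign_amplicon(
    seq: str,
    panel: PanelConfig,
    max_primer_mismatch: int = 2,
) -> Optional[tuple[AmpliconDef, str]]:
    """Identify which amplicon a (index-trimmed) read comes from.

    Returns ``(amplicon, orientation)`` with orientation ``"+"`` when the
    read begins with the forward primer, ``"-"`` when its reverse
    complement does; ``None`` (UNMATCHED) when no primer fits within
    ``max_primer_mismatch`` or two amplicons tie at minimum distance.
    Forward orientation is tried first; the reverse complement is only
    consulted when no forward-orientation primer is acceptable.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")

    def _candidates(oriented: str, orientation: str):
        found = []
        for amp in panel:
            primer = amp.forward_primer
            if not primer or len(oriented) < len(primer):
                continue
            d = hamming(oriented[: len(primer)], primer)
            if d <= max_primer_mismatch:
                found.append((d, amp, orientation))
        return found

    for oriented, orientation in ((seq, "+"), (reverse_complement(seq), "-")):
        found = _candidates(oriented, orientation)
        if not found:
            continue
        best_d = min(d for d, _, _ in found)
        best = [c for c in found if c[0] == best_d]
        if len(best) == 1:
            _, amp, orient = best[0]
            return amp, orient
        return None  # ambiguous at minimum distance
    return None


def call_pattern(
    seq: str,
    amplicon: AmpliconDef,
    read_id: str = "",
    min_identity: float = 0.90,
    max_n: int = 0,
    sample_id: str = "",
    replicate_id: str = "",
    orientation: str = "+",
) -> MethylationCall:
    """Call the methylation pattern of one oriented, primer-trimmed read.

    The read is anchored ungapped at the end of the forward primer, i.e.
    ``seq[0]`` sits at reference position ``amplicon.interior_start``.
    A read too short to cover the last included CpG fails with reason
    ``TOO_SHORT`` (empty pattern). ``passed`` requires identity >=
    ``min_identity`` and at most ``max_n`` no-calls; by default
    (``max_n=0``) any N keeps the read out of downstream pattern tables
    while its fail reason remains visible in QC counts.
    """
    offset = amplicon.interior_start
    included = amplicon.included_sites
    end = offset + len(seq)

    if included and end <= max(s.position for s in included):
        return MethylationCall(
            read_id=read_id,
            amplicon=amplicon.name,
            pattern="",
            k_demethylated=0,
            noncpg_c_total=0,
            noncpg_c_unconverted=0,
            identity_frac=0.0,
            passed=False,
            fail_reason=TOO_SHORT,
            sample_id=sample_id,
            replicate_id=replicate_id,
            orientation=orientation,
        )

    pattern_chars = []
    for site in included:
        i = site.position - offset
        base = seq[i] if 0 <= i < len(seq) else "N"
        pattern_chars.append({"C": "M", "T": "U"}.get(base, "N"))
    pattern = "".join(pattern_chars)

    total = unconverted = 0
    for p in amplicon.noncpg_c_positions:
        i = p - offset
        if 0 <= i < len(seq):
            base = seq[i]
            if base == "C":
                total += 1
                unconverted += 1
            elif base == "T":
                total += 1
            # sequencing errors to A/G are neither converted nor unconverted

    conv_ref = amplicon.converted_reference()
    site_positions = amplicon.site_positions
    id_total = id_match = 0
    for p in range(offset, min(end, amplicon.interior_end)):
        if p in site_positions:
            continue
        id_total += 1
        if seq[p - offset] == conv_ref[p]:
            id_match += 1
    identity = id_match / id_total if id_total else 1.0

    n_count = pattern.count("N")
    passed = identity >= min_identity and n_count <= max_n
    if identity < min_identity:
        reason = LOW_IDENTITY
    elif n_count > max_n:
        reason = TOO_MANY_N
    else:
        reason = ""

    return MethylationCall(
        read_id=read_id,
        amplicon=amplicon.name,
        pattern=pattern,
        k_demethylated=pattern.count("U"),
        noncpg_c_total=total,
        noncpg_c_unconverted=unconverted,
        identity_frac=identity,
        passed=passed,
        fail_reason=reason,
        sample_id=sample_id,
        replicate_id=replicate_id,
        orientation=orientation,
    )


def conversion_efficiency(
    calls: Iterable[MethylationCall],
    amplicon: str = "",
    sample: str = "",
) -> ConversionQC:
    """Aggregate conversion efficiency over the passed calls of one stratum.

    Efficiency is ``100 * (sum converted) / (sum total)`` across passed
    reads' non-CpG cytosine observations. With a zero denominator the
    statistic is undefined and reported as missing (``efficiency=None``)
    with a warning.
    """
    total = unconverted = 0
    for call in calls:
        if not call.passed:
            continue
        total += call.noncpg_c_total
        unconverted += call.noncpg_c_unconverted
    if total == 0:
        warnings.warn(
            f"conversion efficiency undefined for {sample or '<sample>'}/"
            f"{amplicon or '<amplicon>'}: no non-CpG cytosine observations",
            stacklevel=2,
        )
        return ConversionQC(amplicon=amplicon, sample=sample, efficiency=None)
    return ConversionQC(
        amplicon=amplicon,
        sample=sample,
        efficiency=100.0 * (total - unconverted) / total,
        observations=total,
        unconverted=unconverted,
    )
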
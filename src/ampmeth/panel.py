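"""Amplicon panel model: targeted regions and their bisulfite-converted expectations.

A panel describes each PCR amplicon by its genomic reference subsequence
(pre-conversion, top strand), the primers as synthesized against the
bisulfite-converted template, the CpG sites interrogated, and the non-CpG
cytosine positions used for conversion-efficiency QC. Only the converted
top strand is modelled: the assay's primers select a single strand, so
strand choice is a property of the panel, not of individual reads.

Coordinates are 0-based offsets within the amplicon reference; a CpG
site's ``position`` is the cytosine of the CpG dinucleotide. Sites may be
declared but excluded from analysis (e.g. the FOXP3 TSDR site "sA"):
excluded sites are validated like any other CpG but never appear in
pattern output, and — because their methylation state is unknown — they
are also left out of the conversion-QC numerator and denominator.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import yaml

from ampmeth.errors import PanelError, SequenceError, ValidationError

_DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _require_dna(seq: str, context: str) -> None:
    bad = set(seq) - _DNA
    if bad:
        raise SequenceError(f"{context}: non-ACGT character(s) {sorted(bad)!r}")


def bisulfite_convert(reference: str, cpg_methylated: bool) -> str:
    """In-silico bisulfite conversion of a top-strand DNA sequence.

    Every cytosine not followed by guanine deaminates and is read as T.
    A CpG cytosine is protected (stays C) when ``cpg_methylated`` is
    true, otherwise it also reads T. All other bases are unchanged, so
    the output has the same length as the input. A trailing C (no next
    base) cannot be part of a CpG and converts to T.
    """
    if not reference:
        raise SequenceError("bisulfite_convert: empty sequence")
    _require_dna(reference, "bisulfite_convert")
    last = len(reference) - 1
    out = []
    for i, base in enumerate(reference):
        if base == "C":
            if i < last and reference[i + 1] == "G":
                out.append("C" if cpg_methylated else "T")
            else:
                out.append("T")
        else:
            out.append(base)
    return "".join(out)


@lru_cache(maxsize=256)
def _converted_methylated(reference: str) -> str:
    """Cached fully-methylated conversion, reused by the caller on every read."""
    return bisulfite_convert(reference, True)


def strip_adaptor(primer: str) -> str:
    """Drop lowercase adaptor bases from a primer as configured.

    Sample-sheet/primer tables conventionally write the universal adaptor
    tail in lowercase and the gene-specific portion in uppercase; only
    the latter is part of the amplicon model.
    """
    return "".join(c for c in primer if not c.islower())


@dataclass(frozen=True)
class CpGSite:
    """One interrogated CpG dinucleotide within an amplicon.

    ``position`` is the 0-based offset of the CpG cytosine in the
    amplicon reference. ``included`` marks whether the site contributes
    to pattern output (excluded sites are validated but never reported).
    """

    label: str
    position: int
    included: bool = True


@dataclass
class AmpliconDef:
    """One targeted region: reference, primers, CpG sites and QC positions.

    ``noncpg_c_positions`` — the non-methylatable cytosines used for
    conversion QC — are derived automatically as every reference C not
    followed by G, outside the primer-covered ends; if supplied they are
    checked against that derivation.
    """

    name: str
    reference: str
    forward_primer: str = ""
    reverse_primer: str = ""
    cpg_sites: tuple[CpGSite, ...] = ()
    noncpg_c_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        self.forward_primer = strip_adaptor(self.forward_primer)
        self.reverse_primer = strip_adaptor(self.reverse_primer)
        ctx = f"amplicon {self.name!r}"
        _require_dna(self.reference, f"{ctx}: reference")
        _require_dna(self.forward_primer, f"{ctx}: forward_primer")
        _require_dna(self.reverse_primer, f"{ctx}: reverse_primer")
        if not self.reference:
            raise SequenceError(f"{ctx}: empty reference")
        self.cpg_sites = tuple(sorted(self.cpg_sites, key=lambda s: s.position))

        labels = [s.label for s in self.cpg_sites]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"{ctx}: duplicate CpG site labels")

        n = len(self.reference)
        for site in self.cpg_sites:
            p = site.position
            if not (0 <= p < n - 1) or self.reference[p] != "C" or self.reference[p + 1] != "G":
                found = self.reference[p : p + 2] if 0 <= p < n else "<out of range>"
                raise ValidationError(
                    f"{ctx}: site {site.label!r} at position {p} is not a CG dinucleotide "
                    f"(found {found!r})"
                )
            if p < self.interior_start or p + 1 >= self.interior_end:
                raise ValidationError(
                    f"{ctx}: site {site.label!r} at position {p} lies within a primer region"
                )

        self._check_primers(ctx)

        # every CpG between the primers must be declared so that pattern
        # calling and conversion QC partition the interior cytosines
        declared = {s.position for s in self.cpg_sites}
        derived_noncpg = []
        for i in range(self.interior_start, self.interior_end):
            if self.reference[i] != "C":
                continue
            if i + 1 < n and self.reference[i + 1] == "G":
                if i not in declared:
                    raise ValidationError(
                        f"{ctx}: undeclared CpG at interior position {i}; declare it as a "
                        "site (included or excluded)"
                    )
            else:
                derived_noncpg.append(i)
        derived = tuple(derived_noncpg)
        if self.noncpg_c_positions:
            if tuple(sorted(self.noncpg_c_positions)) != derived:
                raise ValidationError(
                    f"{ctx}: noncpg_c_positions disagree with positions derived from the "
                    f"reference (expected {list(derived)})"
                )
            self.noncpg_c_positions = derived
        else:
            self.noncpg_c_positions = derived

    def _check_primers(self, ctx: str) -> None:
        ref = self.reference
        if len(self.forward_primer) + len(self.reverse_primer) >= len(ref):
            raise ValidationError(f"{ctx}: primers cover the whole reference")
        for meth in (True, False):
            conv = bisulfite_convert(ref, meth)
            fwd_ok = (not self.forward_primer) or conv.startswith(self.forward_primer)
            rev_ok = (not self.reverse_primer) or conv.endswith(
                reverse_complement(self.reverse_primer)
            )
            if fwd_ok and rev_ok:
                return
        raise ValidationError(
            f"{ctx}: primers do not match the bisulfite-converted reference ends"
        )

    @property
    def interior_start(self) -> int:
        """First reference position not covered by the forward primer."""
        return len(self.forward_primer)

    @property
    def interior_end(self) -> int:
        """One past the last reference position not covered by the reverse primer."""
        return len(self.reference) - len(self.reverse_primer)

    @property
    def included_sites(self) -> tuple[CpGSite, ...]:
        return tuple(s for s in self.cpg_sites if s.included)

    @property
    def n_included(self) -> int:
        """Number of CpG sites reported per read (pattern length)."""
        return len(self.included_sites)

    @property
    def site_positions(self) -> frozenset[int]:
        return frozenset(s.position for s in self.cpg_sites)

    def converted_reference(self) -> str:
        """Fully-methylated bisulfite conversion of the reference (cached)."""
        return _converted_methylated(self.reference)


def expected_read(amplicon: AmpliconDef, pattern: Sequence[str] | str) -> str:
    """Error-free converted read implied by a per-site methylation pattern.

    ``pattern`` covers *all* declared CpG sites of the amplicon in
    position order, one of ``M`` (methylated, reads C) or ``U``
    (demethylated, reads T) per site. All non-CpG cytosines read T.
    Primer-covered ends are emitted as converted sequence, matching the
    synthesized primers. This is the oracle sequence against which
    pattern calling is exercised.
    """
    states = list(pattern)
    if len(states) != len(amplicon.cpg_sites):
        raise ValidationError(
            f"pattern length {len(states)} != {len(amplicon.cpg_sites)} declared CpG sites"
        )
    chars = list(bisulfite_convert(amplicon.reference, True))
    for site, state in zip(amplicon.cpg_sites, states):
        if state == "M":
            chars[site.position] = "C"
        elif state == "U":
            chars[site.position] = "T"
        else:
            raise ValidationError(f"pattern state must be 'M' or 'U', got {state!r}")
    return "".join(chars)


@dataclass
class PanelConfig:
    """An ordered collection of amplicons analysed together in one run."""

    amplicons: tuple[AmpliconDef, ...]
    version: str = "1"

    def __post_init__(self) -> None:
        self.amplicons = tuple(self.amplicons)
        names = [a.name for a in self.amplicons]
        if len(set(names)) != len(names):
            raise ValidationError("panel: duplicate amplicon names")

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __getitem__(self, name: str) -> AmpliconDef:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.amplicons)


def _site_from_mapping(entry: Mapping, ctx: str) -> CpGSite:
    try:
        return CpGSite(
            label=str(entry["label"]),
            position=int(entry["position"]),
            included=bool(entry.get("included", True)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise PanelError(f"{ctx}: malformed cpg_sites entry {entry!r}: {exc}") from exc


def load_panel(source) -> PanelConfig:
    """Load and validate a panel from YAML (path, text, file-like or mapping).

    The document holds ``version`` and ``amplicons``, each amplicon with
    ``name``, ``reference``, ``forward_primer``, ``reverse_primer`` and
    ``cpg_sites: [{label, position, included}]``. Primer fields may carry
    lowercase adaptor tails, which are stripped. ``noncpg_c_positions``
    is optional and derived from the reference when absent.
    """
    if isinstance(source, Mapping):
        data = source
    else:
        if isinstance(source, (str, os.PathLike)) and (
            not isinstance(source, str) or ("\n" not in source and os.path.exists(source))
        ):
            with open(source) as fh:
                text = fh.read()
        elif hasattr(source, "read"):
            text = source.read()
        else:
            text = source
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise PanelError(f"panel config does not parse as YAML: {exc}") from exc
    if not isinstance(data, Mapping) or "amplicons" not in data:
        raise PanelError("panel config must be a mapping with an 'amplicons' list")

    amplicons = []
    for entry in data["amplicons"]:
        name = str(entry.get("name", "<unnamed>"))
        ctx = f"amplicon {name!r}"
        missing = [k for k in ("name", "reference") if k not in entry]
        if missing:
            raise PanelError(f"{ctx}: missing required field(s) {missing}")
        sites = tuple(_site_from_mapping(s, ctx) for s in entry.get("cpg_sites", []))
        amplicons.append(
            AmpliconDef(
                name=name,
                reference=str(entry["reference"]).strip().upper(),
                forward_primer=str(entry.get("forward_primer", "")).strip(),
                reverse_primer=str(entry.get("reverse_primer", "")).strip(),
                cpg_sites=sites,
                noncpg_c_positions=tuple(entry.get("noncpg_c_positions", ())),
            )
        )
    return PanelConfig(tuple(amplicons), version=str(data.get("version", "1")))


def dump_panel(panel: PanelConfig) -> str:
    """Serialize a panel back to YAML (round-trips through :func:`load_panel`)."""
    doc = {
        "version": panel.version,
        "amplicons": [
            {
                "name": a.name,
                "reference": a.reference,
                "forward_primer": a.forward_primer,
                "reverse_primer": a.reverse_primer,
                "cpg_sites": [
                    {"label": s.label, "position": s.position, "included": s.included}
                    for s in a.cpg_sites
                ],
            }
            for a in panel
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def sites_from_bed(path, amplicon_name: str | None = None) -> tuple[CpGSite, ...]:
    """Read CpG sites from a BED-like file (0-based, half-open intervals).

    Columns: amplicon name, start, end, label, and an optional fifth
    column where ``excluded`` (or ``0``) flags a site that is declared
    but not analysed. The interval must be the 2-bp CpG dinucleotide or
    the 1-bp cytosine; the site position is the interval start.
    """
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelError(f"BED site line needs >=4 columns: {line!r}")
            chrom, start, end, label = fields[:4]
            if amplicon_name is not None and chrom != amplicon_name:
                continue
            if int(end) - int(start) not in (1, 2):
                raise PanelError(f"BED site {label!r} is not a 1- or 2-bp CpG interval")
            included = True
            if len(fields) >= 5 and fields[4].lower() in ("excluded", "0"):
                included = False
            sites.append(CpGSite(label=label, position=int(start), included=included))
    return tuple(sites)
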
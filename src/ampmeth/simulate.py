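"""Seeded simulator for multiplexed bisulfite amplicon reads with known truth.

The generator emulates the data-generating process of the assay at the
molecule level: a sample is a mixture of cell types with distinct
per-CpG methylation profiles (a Treg profile is demethylated at the
TSDR, a naive/effector profile fully methylated); for female samples the
FOXP3 locus is X-linked, so each template molecule is, with probability
1/2, the fully methylated inactive-X copy regardless of cell type.
Bisulfite chemistry converts each unmethylated cytosine to T with
probability ``conversion_rate`` (target >= 0.99; failures read C) and —
off by default — falsely converts methylated cytosines at rate
``inappropriate_conversion``. Sequencing adds uniform per-base
substitution errors. Reads carry their sample index (prepended, per the
demultiplexer's default convention) followed by the full amplicon
sequence starting at the forward primer; qualities are constant high
values since calling ignores them by default.

Everything is deterministic given the design seed; the emitted truth
table pairs each read id with its generating profile and true pattern so
recovery can be checked end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ampmeth.demux import IndexAssignment, SampleSheet
from ampmeth.errors import ConfigError, ValidationError
from ampmeth.panel import AmpliconDef, CpGSite, PanelConfig, reverse_complement

_OTHER_BASES = {b: "ACGT".replace(b, "") for b in "ACGT"}
_OTHER_BASES.update({b: "ACGT" for b in "N"})


@dataclass(frozen=True)
class CellTypeProfile:
    """Per-site methylation probabilities of one cell type, per amplicon.

    ``meth_probs`` maps amplicon name to one probability per declared
    CpG site (position order, included and excluded sites alike): the
    chance that the site is methylated on a molecule from this cell
    type. A canonical Treg profile is all zeros at the TSDR; a naive
    profile all ones.
    """

    name: str
    meth_probs: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        for amp, probs in self.meth_probs.items():
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValidationError(
                    f"profile {self.name!r}: methylation probabilities for {amp!r} "
                    "must be in [0, 1]"
                )


def uniform_profile(name: str, panel: PanelConfig, prob: float) -> CellTypeProfile:
    """A profile with the same methylation probability at every site."""
    return CellTypeProfile(
        name=name,
        meth_probs={a.name: tuple([prob] * len(a.cpg_sites)) for a in panel},
    )


def treg_profile(panel: PanelConfig) -> CellTypeProfile:
    """Fully demethylated profile (Treg-like at every amplicon)."""
    return uniform_profile("treg", panel, 0.0)


def naive_profile(panel: PanelConfig) -> CellTypeProfile:
    """Fully methylated profile (naive/effector-like)."""
    return uniform_profile("naive", panel, 1.0)


@dataclass
class SampleDesign:
    """One biological sample: a mixture of profiles, a sex, and replicates."""

    sample_id: str
    mixture: Mapping[str, float]
    sex: str = "male"
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sample {self.sample_id!r}: sex must be male or female")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"sample {self.sample_id!r}: mixture weights sum to {total}, expected 1"
            )
        if self.n_replicates < 1:
            raise ValidationError(f"sample {self.sample_id!r}: n_replicates must be >= 1")


@dataclass
class SimDesign:
    """Full description of one simulated sequencing run."""

    panel: PanelConfig
    sample_sheet: SampleSheet
    profiles: tuple[CellTypeProfile, ...]
    samples: tuple[SampleDesign, ...]
    conversion_rate: float = 0.995
    inappropriate_conversion: float = 0.0
    seq_error_rate: float = 0.001
    reads_per_replicate: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for rate, name in (
            (self.conversion_rate, "conversion_rate"),
            (self.inappropriate_conversion, "inappropriate_conversion"),
            (self.seq_error_rate, "seq_error_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {rate}")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate profile names")
        by_name = {p.name: p for p in self.profiles}
        sheet_keys = {(a.sample_id, a.replicate_id) for a in self.sample_sheet.assignments}
        for sample in self.samples:
            unknown = set(sample.mixture) - set(by_name)
            if unknown:
                raise ValidationError(
                    f"sample {sample.sample_id!r} mixes unknown profile(s) {sorted(unknown)}"
                )
            for rep in range(1, sample.n_replicates + 1):
                if (sample.sample_id, f"r{rep}") not in sheet_keys:
                    raise ValidationError(
                        f"sample sheet has no index for {sample.sample_id}/r{rep}"
                    )
            for prof_name in sample.mixture:
                prof = by_name[prof_name]
                for amp in self.panel:
                    probs = prof.meth_probs.get(amp.name)
                    if probs is None or len(probs) != len(amp.cpg_sites):
                        raise ValidationError(
                            f"profile {prof_name!r} does not cover amplicon {amp.name!r} "
                            f"({len(amp.cpg_sites)} sites)"
                        )

    def profile(self, name: str) -> CellTypeProfile:
        for p in self.profiles:
            if p.name == name:
                return p
        raise KeyError(name)


def random_index_pool(
    n: int, length: int = 8, min_distance: int = 3, rng: Optional[np.random.Generator] = None
) -> tuple[str, ...]:
    """Draw ``n`` random indexes with pairwise Hamming distance >= ``min_distance``.

    Rejection sampling; a pairwise distance > 2 * max_mismatch guarantees
    zero demultiplexing cross-talk on error-free index regions.
    """
    rng = np.random.default_rng() if rng is None else rng
    pool: list[str] = []
    attempts = 0
    while len(pool) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ValidationError(
                f"could not draw {n} indexes of length {length} at distance {min_distance}"
            )
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if all(sum(a != b for a, b in zip(cand, p)) >= min_distance for p in pool):
            pool.append(cand)
    return tuple(pool)


def build_sample_sheet(
    samples: Sequence[SampleDesign],
    index_length: int = 8,
    seed: int = 0,
    min_distance: int = 3,
) -> SampleSheet:
    """One index per sample x replicate, alternating forward/reverse placement."""
    n_needed = sum(s.n_replicates for s in samples)
    rng = np.random.default_rng(seed)
    pool = random_index_pool(n_needed, length=index_length, min_distance=min_distance, rng=rng)
    assignments = []
    i = 0
    for sample in samples:
        for rep in range(1, sample.n_replicates + 1):
            assignments.append(
                IndexAssignment(
                    index_seq=pool[i],
                    placement="forward" if i % 2 == 0 else "reverse",
                    sample_id=sample.sample_id,
                    replicate_id=f"r{rep}",
                )
            )
            i += 1
    return SampleSheet(tuple(assignments))


def _render_molecule(
    amp: AmpliconDef,
    site_methylated: Sequence[bool],
    rng: np.random.Generator,
    conversion_rate: float,
    inappropriate_conversion: float,
) -> str:
    """Bisulfite-converted sequence of one template molecule (no seq errors).

    Primer-covered ends are emitted as the synthesized primers (always
    fully converted); conversion success is drawn per interior cytosine.
    """
    chars = list(amp.reference)
    state = {s.position: m for s, m in zip(amp.cpg_sites, site_methylated)}
    for p in range(amp.interior_start, amp.interior_end):
        if chars[p] != "C":
            continue
        methylated = state.get(p, False)
        if methylated:
            if rng.random() < inappropriate_conversion:
                chars[p] = "T"
        else:
            if rng.random() < conversion_rate:
                chars[p] = "T"
    fwd = amp.forward_primer
    if fwd:
        chars[: len(fwd)] = list(fwd)
    rev = amp.reverse_primer
    if rev:
        chars[amp.interior_end :] = list(reverse_complement(rev))
    return "".join(chars)


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        alt = _OTHER_BASES[chars[i]]
        chars[i] = alt[rng.integers(0, len(alt))]
    return "".join(chars)


def simulate(design: SimDesign) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Generate one run's reads and its truth table.

    Returns ``(records, truth)`` where ``records`` is a list of
    ``(read_id, sequence, quality)`` FASTQ-ready tuples and ``truth`` a
    DataFrame with one row per read: sample_id, replicate_id, amplicon,
    profile, inactive_x, true_pattern (M/U over *included* sites) and
    fully_demethylated. Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    index_of = {
        (a.sample_id, a.replicate_id): a for a in design.sample_sheet.assignments
    }
    amplicons = list(design.panel)
    records: list[tuple[str, str, str]] = []
    truth_rows = []
    serial = 0
    for sample in design.samples:
        prof_names = sorted(sample.mixture)
        weights = np.array([sample.mixture[p] for p in prof_names])
        profiles = [design.profile(p) for p in prof_names]
        for rep in range(1, sample.n_replicates + 1):
            rep_id = f"r{rep}"
            index = index_of[(sample.sample_id, rep_id)]
            for _ in range(design.reads_per_replicate):
                amp = amplicons[rng.integers(0, len(amplicons))]
                prof = profiles[rng.choice(len(profiles), p=weights)]
                inactive_x = sample.sex == "female" and rng.random() < 0.5
                if inactive_x:
                    meth = [True] * len(amp.cpg_sites)
                else:
                    probs = prof.meth_probs[amp.name]
                    draws = rng.random(len(probs))
                    meth = [d < p for d, p in zip(draws, probs)]
                mol = _render_molecule(
                    amp, meth, rng, design.conversion_rate, design.inappropriate_conversion
                )
                seq = _apply_errors(index.index_seq + mol, rng, design.seq_error_rate)
                read_id = f"{sample.sample_id}.{rep_id}.{amp.name}.{serial:06d}"
                serial += 1
                records.append((read_id, seq, "I" * len(seq)))
                true_pattern = "".join(
                    "M" if m else "U"
                    for s, m in zip(amp.cpg_sites, meth)
                    if s.included
                )
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "sample_id": sample.sample_id,
                        "replicate_id": rep_id,
                        "amplicon": amp.name,
                        "profile": prof.name,
                        "inactive_x": inactive_x,
                        "true_pattern": true_pattern,
                        "fully_demethylated": set(true_pattern) == {"U"},
                    }
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "sample_id",
            "replicate_id",
            "amplicon",
            "profile",
            "inactive_x",
            "true_pattern",
            "fully_demethylated",
        ],
    )
    return records, truth


def truth_demethylated_fraction(truth: pd.DataFrame, amplicon: str | None = None) -> pd.Series:
    """Per-sample fraction of simulated molecules fully demethylated at
    the included sites (optionally restricted to one amplicon)."""
    df = truth if amplicon is None else truth[truth["amplicon"] == amplicon]
    return df.groupby("sample_id")["fully_demethylated"].mean()


def titration_design(
    p_values: Sequence[float],
    reads_per_point: int,
    seed: int = 0,
    panel: Optional[PanelConfig] = None,
    index_length: int = 8,
    conversion_rate: float = 0.995,
    seq_error_rate: float = 0.001,
) -> list[SimDesign]:
    """One single-sample male design per Treg mixture fraction.

    Emulates a defined Treg / naive CD4+ titration series: sample ``i``
    mixes an all-demethylated Treg profile at weight ``p_values[i]`` with
    an all-methylated naive profile. Per-point seeds are derived from
    ``seed`` so the series is reproducible yet points are independent.
    """
    if panel is None:
        panel = PanelConfig((synthetic_panel().amplicons[0],), version="titration")
    children = np.random.SeedSequence(seed).spawn(len(p_values))
    designs = []
    for i, (p, child) in enumerate(zip(p_values, children)):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"titration fraction {p} outside [0, 1]")
        sample = SampleDesign(
            sample_id=f"mix{i:02d}", mixture={"treg": p, "naive": 1.0 - p}, sex="male"
        )
        point_seed = int(child.generate_state(1)[0] % (2**31))
        sheet = build_sample_sheet([sample], index_length=index_length, seed=point_seed)
        designs.append(
            SimDesign(
                panel=panel,
                sample_sheet=sheet,
                profiles=(treg_profile(panel), naive_profile(panel)),
                samples=(sample,),
                conversion_rate=conversion_rate,
                seq_error_rate=seq_error_rate,
                reads_per_replicate=reads_per_point,
                seed=point_seed,
            )
        )
    return designs


def _random_reference(
    rng: np.random.Generator, length: int, cpg_positions: Sequence[int]
) -> str:
    """Random ACGT sequence with CG dinucleotides exactly at the given positions."""
    cpg = set(cpg_positions)
    gpos = {p + 1 for p in cpg}
    bases: list[str] = []
    for i in range(length):
        if i in cpg:
            bases.append("C")
            continue
        if i in gpos:
            bases.append("G")
            continue
        choices = "ACGT"
        if bases and bases[-1] == "C":
            choices = choices.replace("G", "")  # no accidental CpG
        if i + 1 in gpos:
            choices = choices.replace("C", "")  # next base is a site's G
        bases.append(choices[rng.integers(0, len(choices))])
    # a trailing or pre-primer C is harmless (non-CpG) but avoid C right
    # before a designated C? not needed: C before C never forms CG
    return "".join(bases)


def _synthetic_amplicon(
    rng: np.random.Generator,
    name: str,
    site_labels: Sequence[str],
    excluded: frozenset[str] | set[str],
    length: int,
    primer_len: int,
) -> AmpliconDef:
    interior = (primer_len + 4, length - primer_len - 4)
    positions = np.linspace(interior[0], interior[1] - 2, num=len(site_labels)).astype(int)
    # enforce >= 4 bp spacing so sites never collide
    for i in range(1, len(positions)):
        positions[i] = max(positions[i], positions[i - 1] + 4)
    ref = _random_reference(rng, length, positions)
    from ampmeth.panel import bisulfite_convert  # local import to avoid cycle at module load

    conv = bisulfite_convert(ref, True)
    return AmpliconDef(
        name=name,
        reference=ref,
        forward_primer=conv[:primer_len],
        reverse_primer=reverse_complement(conv[-primer_len:]),
        cpg_sites=tuple(
            CpGSite(label=lab, position=int(pos), included=lab not in excluded)
            for lab, pos in zip(site_labels, positions)
        ),
    )


def synthetic_panel(seed: int = 11) -> PanelConfig:
    """Two-amplicon demonstration panel with *synthetic* sequences.

    Mirrors the structure of the assay's production panel — a TSDR-like
    amplicon declaring ten CpG sites of which "sA" is excluded (nine
    reported per read) and a CTLA4-exon-2-like amplicon with seven sites
    — but the reference sequences are randomly generated stand-ins, not
    the genomic loci. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    foxp3 = _synthetic_amplicon(
        rng,
        "FOXP3_TSDR",
        site_labels=["sA"] + [str(i) for i in range(1, 10)],
        excluded={"sA"},
        length=170,
        primer_len=22,
    )
    ctla4 = _synthetic_amplicon(
        rng,
        "CTLA4_ex2",
        site_labels=[str(i) for i in range(1, 8)],
        excluded=set(),
        length=150,
        primer_len=22,
    )
    return PanelConfig((foxp3, ctla4), version="synthetic-1")


def write_fastq(records: Sequence[tuple[str, str, str]], path) -> None:
    """Write ``(read_id, seq, qual)`` records as FASTQ (gzip if path ends .gz)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def design_from_dict(doc: Mapping, panel: Optional[PanelConfig] = None) -> SimDesign:
    """Build a :class:`SimDesign` from a plain-mapping (YAML) description.

    Schema::

        panel: synthetic | <path to panel YAML>   # ignored when panel= given
        index_length: 8
        conversion_rate: 0.995
        inappropriate_conversion: 0.0
        seq_error_rate: 0.001
        reads_per_replicate: 2000
        seed: 0
        profiles:
          - {name: treg, methylation: 0.0}        # scalar -> every site
          - {name: naive, methylation: 1.0}
          - {name: custom, methylation: {FOXP3_TSDR: [0,0,1,...], ...}}
        samples:
          - {sample_id: S1, sex: male, n_replicates: 2, mixture: {treg: .3, naive: .7}}
    """
    from ampmeth.panel import load_panel

    if panel is None:
        spec = doc.get("panel", "synthetic")
        panel = synthetic_panel() if spec == "synthetic" else load_panel(spec)
    profiles = []
    for entry in doc.get("profiles", ()):
        meth = entry["methylation"]
        if isinstance(meth, Mapping):
            profiles.append(
                CellTypeProfile(entry["name"], {k: tuple(v) for k, v in meth.items()})
            )
        else:
            profiles.append(uniform_profile(entry["name"], panel, float(meth)))
    samples = tuple(
        SampleDesign(
            sample_id=str(s["sample_id"]),
            mixture={str(k): float(v) for k, v in s["mixture"].items()},
            sex=str(s.get("sex", "male")),
            n_replicates=int(s.get("n_replicates", 1)),
        )
        for s in doc.get("samples", ())
    )
    if not samples:
        raise ConfigError("simulation design declares no samples")
    seed = int(doc.get("seed", 0))
    sheet = build_sample_sheet(
        samples, index_length=int(doc.get("index_length", 8)), seed=seed
    )
    return SimDesign(
        panel=panel,
        sample_sheet=sheet,
        profiles=tuple(profiles),
        samples=samples,
        conversion_rate=float(doc.get("conversion_rate", 0.995)),
        inappropriate_conversion=float(doc.get("inappropriate_conversion", 0.0)),
        seq_error_rate=float(doc.get("seq_error_rate", 0.001)),
        reads_per_replicate=int(doc.get("reads_per_replicate", 2000)),
        seed=seed,
    )
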
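"""Synthetic diazotroph community generator.

Builds reference NifH peptide/nucleotide panels spanning the canonical
nifH phylogenetic clusters (plus a BchL-like outgroup), and simulates
multi-habitat 454-style amplicon datasets and qPCR experiments with full
ground truth, so that every downstream stage of the pipeline can be
validated without real sequencing data.

The read simulator emulates the features of pyrosequencing amplicons that
matter to the analysis: primer flanks, substitution errors, and
single-base homopolymer indels that shift the reading frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# One codon per amino acid is enough for panel construction; the generator
# draws among all synonymous codons so nucleotide panels are degenerate.
_CODONS: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _cod = _b1 + _b2 + _b3
            _aa = str(Seq(_cod).translate())
            if _aa in AMINO_ACIDS:
                _CODONS.setdefault(_aa, []).append(_cod)

# Literal (disambiguated) realizations of the nifH1/nifH2 priming sites
# used as default read flanks; cropping is exact prefix/suffix removal.
DEFAULT_FORWARD_FLANK = "TGCGACCCTAAGGCTGA"
DEFAULT_REVERSE_FLANK = "ACTGCCATCATTTCACC"


@dataclass(frozen=True)
class PanelEntry:
    taxon: str
    cluster: str  # one of "I".."V" or "outgroup"
    peptide: str
    nucleotides: str


@dataclass
class ReferencePanel:
    """Reference NifH sequences with canonical-cluster labels.

    Every peptide has the same window length W and translates exactly
    (standard code, frame 0) from its nucleotide sequence. Exactly one
    entry carries the "outgroup" label (a BchL-like divergent homolog).
    """

    entries: list[PanelEntry]
    window_length: int

    def __post_init__(self) -> None:
        peps = [e.peptide for e in self.entries]
        if any(len(p) != self.window_length for p in peps):
            raise ValueError("all panel peptides must have the window length")
        for e in self.entries:
            if str(Seq(e.nucleotides).translate()) != e.peptide:
                raise ValueError(f"{e.taxon}: nucleotides do not translate to peptide")
        n_out = sum(e.cluster == "outgroup" for e in self.entries)
        if n_out != 1:
            raise ValueError(f"panel must contain exactly one outgroup entry, got {n_out}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def taxa(self) -> list[str]:
        return [e.taxon for e in self.entries]

    @property
    def ingroup(self) -> list[PanelEntry]:
        return [e for e in self.entries if e.cluster != "outgroup"]

    @property
    def outgroup(self) -> PanelEntry:
        return next(e for e in self.entries if e.cluster == "outgroup")

    def get(self, taxon: str) -> PanelEntry:
        for e in self.entries:
            if e.taxon == taxon:
                return e
        raise KeyError(taxon)

    def peptides(self) -> dict[str, str]:
        return {e.taxon: e.peptide for e in self.entries}


def _mutate_peptide(rng: np.random.Generator, peptide: str, rate: float) -> str:
    """Substitute round(rate*W) positions, each to a different residue."""
    n_sub = int(round(rate * len(peptide)))
    if n_sub == 0:
        return peptide
    pos = rng.choice(len(peptide), size=n_sub, replace=False)
    chars = list(peptide)
    for i in pos:
        alt = [a for a in AMINO_ACIDS if a != chars[i]]
        chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


def _reverse_translate(rng: np.random.Generator, peptide: str) -> str:
    return "".join(_CODONS[a][rng.integers(len(_CODONS[a]))] for a in peptide)


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatching positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b)) / len(a)


def generate_reference_panel(
    n_taxa: int,
    divergence: float = 0.15,
    seed: int = 0,
    window_length: int = 108,
    clusters: tuple[str, ...] = ("I", "III"),
) -> ReferencePanel:
    """Evolve a NifH reference panel on a two-level star phylogeny.

    Cluster ancestors are derived from a common root at `divergence`
    substitutions/site; taxa within a cluster diverge from their ancestor
    at 0.4*divergence; the outgroup diverges at min(3*divergence, 0.45).
    This guarantees within-cluster < between-cluster < outgroup peptide
    p-distances, which the constructor verifies.

    Parameters
    ----------
    n_taxa : number of ingroup taxa (split round-robin over `clusters`).
    divergence : substitutions per site between root and cluster ancestors.
    seed : RNG seed; panels are byte-identical for a fixed seed.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if not 0.0 < divergence < 0.5:
        raise ValueError("divergence must be in (0, 0.5)")
    within_rate = 0.4 * divergence
    if n_taxa > len(clusters) and int(round(within_rate * window_length)) == 0:
        raise ValueError(
            "divergence too small to generate distinct taxa within a cluster"
        )
    rng = np.random.default_rng(seed)
    root = "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=window_length))

    entries: list[PanelEntry] = []
    seen: set[str] = set()
    anc = {c: _mutate_peptide(rng, root, divergence) for c in clusters}
    for i in range(n_taxa):
        cl = clusters[i % len(clusters)]
        pep = None
        for _ in range(200):
            cand = _mutate_peptide(rng, anc[cl], within_rate) if n_taxa > 1 else anc[cl]
            if cand not in seen:
                pep = cand
                break
        if pep is None:
            raise ValueError("cannot generate enough distinct taxa at this divergence")
        seen.add(pep)
        taxon = f"taxon{i + 1:03d}_{cl}"
        entries.append(PanelEntry(taxon, cl, pep, _reverse_translate(rng, pep)))

    out_pep = _mutate_peptide(rng, root, min(3.0 * divergence, 0.45))
    entries.append(
        PanelEntry("BchL_outgroup", "outgroup", out_pep, _reverse_translate(rng, out_pep))
    )
    panel = ReferencePanel(entries, window_length)
    _check_divergence_ordering(panel)
    return panel


def _check_divergence_ordering(panel: ReferencePanel) -> None:
    ingroup = panel.ingroup
    out = panel.outgroup
    if len(ingroup) < 2:
        return
    max_in = max(
        p_distance(a.peptide, b.peptide)
        for i, a in enumerate(ingroup)
        for b in ingroup[i + 1 :]
    )
    min_out = min(p_distance(out.peptide, e.peptide) for e in ingroup)
    if min_out <= max_in:
        raise ValueError(
            "outgroup is not more divergent than the ingroup spread; "
            "retry with a different seed or lower divergence"
        )


# ---------------------------------------------------------------------------
# Community / read simulation
# ---------------------------------------------------------------------------


@dataclass
class HabitatSpec:
    """One habitat of the sampling design (e.g. a soil or a rhizosphere)."""

    name: str
    richness: int
    n_replicates: int = 4
    depth_range: tuple[int, int] = (600, 800)
    lognormal_sigma: float = 1.2
    differential: dict[str, float] = field(default_factory=dict)  # taxon -> fold change
    taxa: list[str] | None = None  # explicit membership; drawn from panel if None

    def validate(self) -> None:
        if self.richness < 1:
            raise ValueError(f"{self.name}: richness must be >= 1")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] < 1:
            raise ValueError(f"{self.name}: invalid depth range")
        if any(f <= 0 for f in self.differential.values()):
            raise ValueError(f"{self.name}: fold changes must be > 0")


@dataclass
class ErrorModel:
    substitution_rate: float = 0.0  # per base, inside the amplified region
    indel_rate: float = 0.0  # per read: prob. of one homopolymer indel
    mean_quality: float = 32.0
    quality_sd: float = 4.0

    def validate(self) -> None:
        for r in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must be in [0, 1]")


@dataclass
class CommunitySpec:
    habitats: list[HabitatSpec]
    error_model: ErrorModel = field(default_factory=ErrorModel)
    forward_flank: str = DEFAULT_FORWARD_FLANK
    reverse_flank: str = DEFAULT_REVERSE_FLANK
    seed: int = 0


@dataclass
class SimRead:
    """A simulated amplicon read with per-base Phred qualities."""

    id: str
    sample: str
    nucleotides: str
    qualities: np.ndarray  # int array, len == len(nucleotides)


@dataclass
class GroundTruth:
    read_taxon: dict[str, list[tuple[str, str]]]  # sample -> [(read id, taxon)]
    habitat_abundance: dict[str, dict[str, float]]  # habitat -> taxon -> rel. abund.
    differential_taxa: dict[str, set[str]]  # habitat -> taxa with fold effects
    sample_habitat: dict[str, str]


def _longest_homopolymer(seq: str) -> tuple[int, int]:
    """Return (start, length) of the longest homopolymer run (leftmost)."""
    best_start, best_len = 0, 1
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = i
    return best_start, best_len


def _apply_errors(rng: np.random.Generator, insert: str, em: ErrorModel) -> str:
    bases = "ACGT"
    chars = list(insert)
    if em.substitution_rate > 0:
        hits = np.nonzero(rng.random(len(chars)) < em.substitution_rate)[0]
        for i in hits:
            alt = [b for b in bases if b != chars[i]]
            chars[i] = alt[rng.integers(3)]
    seq = "".join(chars)
    if em.indel_rate > 0 and rng.random() < em.indel_rate:
        start, length = _longest_homopolymer(seq)
        pos = start + int(rng.integers(length))
        if rng.random() < 0.5:  # insertion of an extra run base
            seq = seq[: pos + 1] + seq[pos] + seq[pos + 1 :]
        else:  # deletion of one run base
            seq = seq[:pos] + seq[pos + 1 :]
    return seq


def _habitat_abundances(
    rng: np.random.Generator, hab: HabitatSpec, panel: ReferencePanel
) -> tuple[list[str], np.ndarray]:
    pool = [e.taxon for e in panel.ingroup]
    if hab.richness > len(pool):
        raise ValueError(f"{hab.name}: richness {hab.richness} exceeds panel size {len(pool)}")
    if hab.taxa is not None:
        unknown = set(hab.taxa) - set(pool)
        if unknown:
            raise ValueError(f"{hab.name}: unknown taxa {sorted(unknown)}")
        taxa = list(hab.taxa)
    else:
        taxa = list(rng.choice(pool, size=hab.richness, replace=False))
    unknown = set(hab.differential) - set(panel.taxa)
    if unknown:
        raise ValueError(f"{hab.name}: differential effect on unknown taxa {sorted(unknown)}")
    weights = rng.lognormal(mean=0.0, sigma=hab.lognormal_sigma, size=len(taxa))
    for i, t in enumerate(taxa):
        if t in hab.differential:
            weights[i] *= hab.differential[t]
    return taxa, weights / weights.sum()


def simulate_reads(
    panel: ReferencePanel, spec: CommunitySpec
) -> tuple[dict[str, list[SimRead]], GroundTruth]:
    """Simulate per-sample FASTQ-style reads with full ground truth.

    With all error rates zero, every read is exactly flank + panel
    nucleotide sequence + flank, so the downstream pipeline must recover
    the community structure perfectly.
    """
    spec.error_model.validate()
    rng = np.random.default_rng(spec.seed)
    reads: dict[str, list[SimRead]] = {}
    truth = GroundTruth({}, {}, {}, {})
    for hab in spec.habitats:
        hab.validate()
        taxa, props = _habitat_abundances(rng, hab, panel)
        truth.habitat_abundance[hab.name] = dict(zip(taxa, props.tolist()))
        truth.differential_taxa[hab.name] = set(hab.differential)
        for r in range(hab.n_replicates):
            sample = f"{hab.name}-{r + 1}"
            truth.sample_habitat[sample] = hab.name
            depth = int(rng.integers(hab.depth_range[0], hab.depth_range[1] + 1))
            counts = rng.multinomial(depth, props)
            sample_reads: list[SimRead] = []
            pairs: list[tuple[str, str]] = []
            idx = 0
            for taxon, n in zip(taxa, counts):
                template = panel.get(taxon).nucleotides
                for _ in range(int(n)):
                    idx += 1
                    rid = f"{sample}_r{idx:06d}"
                    insert = _apply_errors(rng, template, spec.error_model)
                    seq = spec.forward_flank + insert + spec.reverse_flank
                    q = int(
                        np.clip(
                            round(rng.normal(spec.error_model.mean_quality, spec.error_model.quality_sd)),
                            2,
                            40,
                        )
                    )
                    sample_reads.append(
                        SimRead(rid, sample, seq, np.full(len(seq), q, dtype=int))
                    )
                    pairs.append((rid, taxon))
            # shuffle so taxa are interleaved as on a real plate
            order = rng.permutation(len(sample_reads))
            reads[sample] = [sample_reads[i] for i in order]
            truth.read_taxon[sample] = [pairs[i] for i in order]
    return reads, truth


def habitat_abundances(
    panel: ReferencePanel, habitat: HabitatSpec, seed: int
) -> tuple[list[str], np.ndarray]:
    """Draw one realization of a habitat's taxon set and relative abundances."""
    habitat.validate()
    return _habitat_abundances(np.random.default_rng(seed), habitat, panel)


def study_soil_habitats() -> list[HabitatSpec]:
    """The two-soil contrast of the study design at full scale.

    Desert soil: 118 taxa, strongly uneven (lognormal sigma 2.0, a few
    dominant rhizobia); agricultural soil: 290 taxa, more even (sigma
    1.2). Depths fixed at the 5217-read soil normalization level.
    """
    return [
        HabitatSpec("desert_soil", richness=118, n_replicates=4,
                    depth_range=(5217, 5217), lognormal_sigma=2.0),
        HabitatSpec("field_soil", richness=290, n_replicates=4,
                    depth_range=(5217, 5217), lognormal_sigma=1.2),
    ]


def study_plant_habitats() -> list[HabitatSpec]:
    """Three plant rhizospheres at the 553-read normalization depth."""
    return [
        HabitatSpec(name, richness=100, n_replicates=4,
                    depth_range=(553, 553), lognormal_sigma=1.2)
        for name in ("M_chamomilla", "C_officinalis", "S_distichum")
    ]


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------


def simulate_qpcr(
    true_copies: dict[str, float],
    slope: float = -3.3219,
    intercept: float = 38.0,
    ct_noise_sd: float = 0.2,
    replicate_design: tuple[int, int] = (2, 3),
    dilution_copies: tuple[float, ...] = (1e7, 1e6, 1e5, 1e4, 1e3, 1e2),
    standard_replicates: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate Ct tables plus a 10-fold dilution-series standard.

    Ct = intercept + slope*log10(copies) + N(0, ct_noise_sd). Each sample
    is measured in `replicate_design` = (duplicates, independent runs),
    the qPCR layout of the study design; each dilution point of the
    standard is measured `standard_replicates` times (default: the same
    duplicates-times-runs design as the samples), as standards are run
    alongside samples on every plate.
    """
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    if any(c <= 0 for c in true_copies.values()):
        bad = sorted(s for s, c in true_copies.items() if c <= 0)
        raise ValueError(f"non-positive copy numbers for samples: {bad}")
    if len(dilution_copies) < 5:
        raise ValueError("dilution series must span at least 5 ten-fold steps")
    rng = np.random.default_rng(seed)
    n_dup, n_runs = replicate_design
    rows = []
    for sample, copies in true_copies.items():
        ct0 = intercept + slope * np.log10(copies)
        for run in range(1, n_runs + 1):
            for dup in range(1, n_dup + 1):
                rows.append(
                    {
                        "sample": sample,
                        "run": run,
                        "duplicate": dup,
                        "ct": ct0 + rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else ct0,
                    }
                )
    ct_table = pd.DataFrame(rows)
    std_rows = []
    for copies in dilution_copies:
        ct0 = intercept + slope * np.log10(copies)
        for _ in range(standard_replicates):
            std_rows.append(
                {
                    "copies": copies,
                    "ct": ct0 + rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else ct0,
                }
            )
    return ct_table, pd.DataFrame(std_rows)


def panel_to_fasta(panel: ReferencePanel, path, what: str = "peptide") -> None:
    """Write panel peptides or nucleotides as FASTA."""
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = []
    for e in panel.entries:
        seq = e.peptide if what == "peptide" else e.nucleotides
        recs.append(SeqRecord(Seq(seq), id=e.taxon, description=f"cluster={e.cluster}"))
    SeqIO.write(recs, path, "fasta")


def reads_to_fastq(reads: dict[str, list[SimRead]], path) -> None:
    """Write all samples' reads to one FASTQ (Phred+33); sample in the header."""
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = []
    for sample in reads:
        for r in reads[sample]:
            rec = SeqRecord(Seq(r.nucleotides), id=r.id, description=f"sample={sample}")
            rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
            recs.append(rec)
    SeqIO.write(recs, path, "fastq")
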
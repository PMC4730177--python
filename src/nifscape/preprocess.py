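"""Read preprocessing: quality filtering, primer cropping, frameshift-aware
translation against a reference panel, window clipping and depth
normalization by subsampling.

The translation step re-implements, in simplified form, the strategy of
frameshift-correcting translators for protein-coding amplicons: each read
is aligned to its closest reference nucleotide sequence, single-base
indels (the dominant pyrosequencing artifact, arising in homopolymer
runs) are repaired up to a configurable budget, and the repaired read is
translated in the reference frame. Reads that align too poorly, need too
many repairs, or still translate with an internal stop are rejected with
machine-readable reasons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .synthcomm import ReferencePanel, SimRead

AmpliconRead = SimRead  # one sequencing read: id, sample, nucleotides, qualities


@dataclass
class PeptideFragment:
    """A frame-corrected NifH peptide in reference coordinates.

    `window` is the 0-based half-open amino-acid interval of the reference
    covered by the peptide; `frame_corrections` counts repaired indels.
    """

    read_id: str
    sample: str
    peptide: str
    frame_corrections: int
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if "*" in self.peptide:
            raise ValueError(f"{self.read_id}: internal stop codon in peptide")


@dataclass(frozen=True)
class Rejection:
    read_id: str
    stage: str
    reason: str


def rejections_to_frame(rejections: list[Rejection]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.read_id, r.stage, r.reason) for r in rejections],
        columns=["read_id", "stage", "reason"],
    )


def quality_filter(
    reads: list[AmpliconRead], min_mean_q: float = 20.0, min_len: int = 200
) -> tuple[list[AmpliconRead], list[Rejection]]:
    """Retain reads with mean Phred >= min_mean_q and length >= min_len.

    Both thresholds are inclusive; reads shorter than `min_len`
    nucleotides are removed. Order is preserved and idempotent.
    """
    kept: list[AmpliconRead] = []
    rejected: list[Rejection] = []
    for r in reads:
        if len(r.nucleotides) < min_len:
            rejected.append(Rejection(r.id, "quality_filter", "too_short"))
        elif float(np.mean(r.qualities)) < min_mean_q:
            rejected.append(Rejection(r.id, "quality_filter", "low_quality"))
        else:
            kept.append(r)
    return kept, rejected


def crop_primers(
    reads: list[AmpliconRead], forward: str, reverse: str
) -> tuple[list[AmpliconRead], list[Rejection]]:
    """Remove one exact copy of each terminal primer.

    Reads lacking the forward primer prefix are dropped; the reverse
    primer is stripped when present at the 3' end. Internal primer
    occurrences are left untouched.
    """
    if not forward or not reverse:
        raise ValueError("primers must be non-empty")
    kept: list[AmpliconRead] = []
    rejected: list[Rejection] = []
    for r in reads:
        seq = r.nucleotides
        if len(forward) > len(seq):
            rejected.append(Rejection(r.id, "crop_primers", "primer_longer_than_read"))
            continue
        if not seq.startswith(forward):
            rejected.append(Rejection(r.id, "crop_primers", "primer_missing"))
            continue
        start, end = len(forward), len(seq)
        if seq.endswith(reverse) and end - len(reverse) >= start:
            end -= len(reverse)
        kept.append(
            AmpliconRead(r.id, r.sample, seq[start:end], np.asarray(r.qualities)[start:end])
        )
    return kept, rejected


_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _repair_from_cigar(read: str, ref: str, cigar: str, ref_start: int) -> tuple[str, int]:
    """Undo read indels relative to the reference; return (repaired, n_repairs).

    In edlib's CIGAR with query=read / target=reference, `I` consumes the
    read (an extra read base: delete it) and `D` consumes the reference
    (a missing read base: restore the reference base).
    """
    out: list[str] = []
    qi, ti = 0, ref_start
    repairs = 0
    for n_s, op in _CIGAR_RE.findall(cigar):
        n = int(n_s)
        if op in "=X":
            out.append(read[qi : qi + n])
            qi += n
            ti += n
        elif op == "I":  # extra base(s) in the read
            qi += n
            repairs += n
        else:  # "D": base(s) missing from the read
            out.append(ref[ti : ti + n])
            ti += n
            repairs += n
    return "".join(out), repairs


def frame_translate(
    read: AmpliconRead,
    panel: ReferencePanel,
    max_repairs: int = 2,
    min_identity: float = 0.7,
) -> PeptideFragment | Rejection:
    """Translate a cropped read into its NifH peptide, repairing frameshifts.

    The read is aligned (infix mode) against every panel nucleotide
    sequence; the best-scoring reference guides up to `max_repairs`
    single-base indel repairs, after which the read is translated in the
    reference frame. Returns a PeptideFragment or a Rejection.
    """
    if len(panel) == 0:
        raise ValueError("empty reference panel")
    seq = read.nucleotides
    if len(seq) < 3:
        return Rejection(read.id, "frame_translate", "no_credible_frame")
    # distance-only pass with a shrinking band picks the closest reference
    max_dist = int((1.0 - min_identity) * len(seq))
    best_entry, best_dist = None, max_dist + 1
    for entry in panel.entries:
        aln = edlib.align(seq, entry.nucleotides, task="distance", mode="HW", k=best_dist - 1)
        d = aln["editDistance"]
        if d != -1 and d < best_dist:
            best_entry, best_dist = entry, d
            if d == 0:
                break
    if best_entry is None:
        return Rejection(read.id, "frame_translate", "no_credible_frame")
    entry = best_entry
    aln = edlib.align(seq, entry.nucleotides, task="path", mode="HW")
    ref_start = aln["locations"][0][0]
    repaired, n_repairs = _repair_from_cigar(seq, entry.nucleotides, aln["cigar"], ref_start)
    if n_repairs > max_repairs:
        return Rejection(read.id, "frame_translate", "excess_frameshifts")
    # trim to codon boundaries of the reference frame
    lead = (3 - ref_start % 3) % 3
    usable = len(repaired) - lead
    if usable < 3:
        return Rejection(read.id, "frame_translate", "no_credible_frame")
    codon_start = ref_start + lead
    n_codons = usable // 3
    peptide = str(Seq(repaired[lead : lead + 3 * n_codons]).translate())
    if "*" in peptide:
        return Rejection(read.id, "frame_translate", "internal_stop")
    aa_start = codon_start // 3
    return PeptideFragment(read.id, read.sample, peptide, n_repairs, (aa_start, aa_start + n_codons))


def translate_all(
    reads: list[AmpliconRead], panel: ReferencePanel, max_repairs: int = 2, min_identity: float = 0.7
) -> tuple[list[PeptideFragment], list[Rejection]]:
    fragments: list[PeptideFragment] = []
    rejections: list[Rejection] = []
    for r in reads:
        res = frame_translate(r, panel, max_repairs=max_repairs, min_identity=min_identity)
        (fragments if isinstance(res, PeptideFragment) else rejections).append(res)
    return fragments, rejections


def clip_to_window(
    fragments: list[PeptideFragment],
    panel: ReferencePanel,
    window_len: int = 108,
) -> tuple[list[PeptideFragment], list[Rejection]]:
    """Clip fragments to the shared reference window [0, window_len).

    Fragments not fully spanning the window are dropped; survivors are
    all exactly `window_len` residues and cover identical coordinates.
    """
    if window_len > panel.window_length:
        raise ValueError(
            f"window_len {window_len} exceeds panel window {panel.window_length}"
        )
    kept: list[PeptideFragment] = []
    rejected: list[Rejection] = []
    for f in fragments:
        s, e = f.window
        if s > 0 or e < window_len:
            rejected.append(Rejection(f.read_id, "clip_to_window", "incomplete_window"))
            continue
        kept.append(
            PeptideFragment(
                f.read_id, f.sample, f.peptide[: window_len - s], f.frame_corrections, (0, window_len)
            )
        )
    return kept, rejected


def subsample_normalize(
    fragments_by_sample: dict[str, list[PeptideFragment]],
    depth: int,
    seed: int = 0,
) -> dict[str, list[PeptideFragment]]:
    """Draw exactly `depth` fragments per sample, uniformly without replacement.

    Fails up front, naming every sample whose depth is insufficient.
    Deterministic for a fixed seed regardless of dict iteration order.
    """
    shallow = sorted(s for s, fr in fragments_by_sample.items() if len(fr) < depth)
    if shallow:
        raise ValueError(
            f"samples with fewer than {depth} fragments: {shallow}"
        )
    out: dict[str, list[PeptideFragment]] = {}
    for sample in sorted(fragments_by_sample):
        frs = fragments_by_sample[sample]
        sub = np.frombuffer(sample.encode(), dtype=np.uint8).sum()
        rng = np.random.default_rng([seed, int(sub)])
        idx = np.sort(rng.choice(len(frs), size=depth, replace=False))
        out[sample] = [frs[i] for i in idx]
    return out


def fragments_to_fasta(fragments: list[PeptideFragment], path) -> None:
    """Peptides as FASTA, one record per fragment, sample encoded in header."""
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = [
        SeqRecord(Seq(f.peptide), id=f.read_id, description=f"sample={f.sample}")
        for f in fragments
    ]
    SeqIO.write(recs, path, "fasta")
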
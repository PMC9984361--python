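"""Synthetic transcriptome, annotation, SL repertoire and read simulator.

The simulator reproduces the library artifact that dominates direct-cDNA
Nanopore runs of trans-spliced transcriptomes: the spliced leader (or an
endogenous 5' stem) at the mRNA 5' end self-primes second-strand synthesis,
producing a covalent hairpin cDNA of which only the first (antisense) strand
base-calls well.  In reference orientation such a read is

    [second-strand copy][partial antisense stem][SL (if trans-spliced)]
    [transcript body][polyA]

where everything left of the body is soft-clipped by a transcriptome
aligner, the copy+stem portion carries second-strand error/quality and the
rest first-strand error/quality.  Every read comes with a truth record and
an oracle SAM emitter with bit-predictable CIGARs, so the full analysis
pipeline runs without an external aligner.

Mechanistic detail: the first-strand cDNA 3' end (reverse complement of the
mRNA 5' GG) folds back onto the CC within the CCC motif ~12 nt into the SL
(or onto the analogous stem of a hairpin gene), so the second strand copies
the template from mRNA position ``fold_offset`` (default 12) onward.  The
copied length is drawn uniformly per read, which is what spreads the
observed soft-clip lengths.

Synthetic spliced leaders are generated with the SL1-like structural
properties (22 nt, 5' GG, central CCC) rather than any organism's real
sequences, and transcript bodies are rejection-sampled so that no SL (or
its reverse complement) can be detected in them — detection tests on the
simulated data are therefore unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .hairpin_detection import PROBE_CLIP_NT, revcomp
from .sl_detection import Repertoire, ScoringScheme, default_threshold, detect_sl

ARTIFACT_HAIRPIN = "hairpin_cDNA_antisense"
ARTIFACT_SENSE = "sense_read"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
SEGMENT_NAMES = ("copy", "stem", "sl", "body", "polya")


class LayoutError(ValueError):
    """Raised when the requested genes cannot fit on the contig."""


@dataclass
class SimConfig:
    """All tunables of the simulator; a fixed seed gives byte-identical output.

    ``err_*`` are total per-base error rates on each strand of the hairpin
    molecule, split into substitutions/insertions/deletions by the ``*_frac``
    fields; ``q_*`` are the mean emitted PHRED scores per strand.
    """

    seed: int = 0
    n_genes: int = 30
    contig: str = "chrS"
    contig_len: int | None = None          # None: sized to fit the layout
    operon_fraction: float = 0.15          # genes placed ~sl2_distance_mode downstream of a neighbor
    sl2_distance_mode: int = 100           # target operonic spacing, nt
    spacing_jitter: int = 15               # uniform jitter on operonic spacing
    isolated_gap_range: tuple[int, int] = (500, 3000)
    endogenous_hairpin_fraction: float = 0.15
    hairpin_artifact_prob: float = 0.95    # P(read molecule is a hairpin cDNA)
    err_first_strand: float = 0.05
    err_second_strand: float = 0.15
    sub_frac: float = 0.6
    ins_frac: float = 0.2
    del_frac: float = 0.2
    q_aligned: float = 14.0
    q_softclip: float = 7.0
    q_sd: float = 3.0
    reads_per_gene: float = 50.0           # mean; total reads = n_genes * reads_per_gene
    sl_length: int = 22
    n_sl2_variants: int = 11
    sl_weights: dict[str, float] | None = None   # within-family sampling weights
    operon_sl2_prob: float = 0.9           # P(SL2 family | operonic gene)
    isolated_sl2_prob: float = 0.02        # P(SL2 family | isolated gene)
    fold_offset: int = 12                  # mRNA position where the fold-back pairs
    copy_len_range: tuple[int, int] = (150, 500)
    polya_len: int = 25
    tx_len_range: tuple[int, int] = (300, 900)

    def __post_init__(self) -> None:
        for name in ("operon_fraction", "endogenous_hairpin_fraction",
                     "hairpin_artifact_prob", "err_first_strand",
                     "err_second_strand", "sub_frac", "ins_frac", "del_frac",
                     "operon_sl2_prob", "isolated_sl2_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.err_second_strand < self.err_first_strand:
            raise ValueError("err_second_strand must be >= err_first_strand")
        if not self.q_aligned > self.q_softclip:
            raise ValueError("q_aligned must exceed q_softclip")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if abs(self.sub_frac + self.ins_frac + self.del_frac - 1.0) > 1e-9:
            raise ValueError("sub/ins/del fractions must sum to 1")


@dataclass
class GeneModel:
    gene_id: str
    transcript_id: str
    contig: str
    start: int       # 1-based inclusive (GFF3 convention)
    end: int
    strand: str
    kind: str        # "sl" (trans-spliced) or "hairpin"
    operonic: bool   # placed ~100 nt downstream of a neighbor
    body: str        # transcript reference sequence


@dataclass
class Reference:
    """Synthetic transcriptome + gene layout + SL repertoire."""

    contig: str
    contig_len: int
    genes: list[GeneModel]
    sls: dict[str, str]

    @property
    def transcripts(self) -> dict[str, str]:
        return {g.transcript_id: g.body for g in self.genes}

    @property
    def tx2gene(self) -> dict[str, str]:
        return {g.transcript_id: g.gene_id for g in self.genes}

    def repertoire(self) -> Repertoire:
        return Repertoire(dict(self.sls))

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "transcriptome": outdir / "transcriptome.fa",
            "annotation": outdir / "genes.gff3",
            "sls": outdir / "sls.fa",
        }
        with open(paths["transcriptome"], "w") as fh:
            for g in self.genes:
                fh.write(f">{g.transcript_id}\n{g.body}\n")
        with open(paths["sls"], "w") as fh:
            for name, seq in self.sls.items():
                fh.write(f">{name}\n{seq}\n")
        with open(paths["annotation"], "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.contig} 1 {self.contig_len}\n")
            for g in self.genes:
                attrs = f"ID={g.gene_id};biotype=protein_coding"
                fh.write(f"{self.contig}\tslclip_sim\tgene\t{g.start}\t{g.end}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")
                fh.write(f"{self.contig}\tslclip_sim\tmRNA\t{g.start}\t{g.end}\t.\t"
                         f"{g.strand}\t.\tID={g.transcript_id};Parent={g.gene_id}\n")
        return paths


@dataclass
class SimTruthRecord:
    """Per-read ground truth (5' status, artifact, segment layout, CIGAR)."""

    read_id: str
    gene_id: str
    transcript_id: str
    true_class: str        # "SL:<name>" | "endogenous_hairpin" | "none"
    artifact: str          # hairpin_cDNA_antisense | sense_read
    is_antisense: bool
    ref_start: int
    cigar: str
    clip5_len: int
    clip3_len: int
    spans: dict[str, tuple[int, int]]  # read coords, reference orientation
    true_start_offset: int

    @property
    def sl_name(self) -> str | None:
        return self.true_class[3:] if self.true_class.startswith("SL:") else None


@dataclass
class SimRead:
    """One simulated read in sequencing orientation."""

    read_id: str
    seq: str
    quals: np.ndarray  # PHRED ints, sequencing orientation


# ---------------------------------------------------------------------------
# reference generation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def make_default_repertoire(
    rng: np.random.Generator, n_sl2: int = 11, length: int = 22,
    min_pairwise_dist: int = 8,
) -> dict[str, str]:
    """Synthetic SLs with the SL1-like structure: 5' GG, CCC at 10..12.

    Members are rejection-sampled to keep every pair (and every pair with a
    reverse complement) at Hamming distance >= ``min_pairwise_dist`` so that
    zero-noise detection has a unique best hit.
    """
    if length < 15:
        raise ValueError("SL length must be >= 15 for the GG/CCC structure")
    names = ["SL1"] + [f"SL2.{i}" for i in range(1, n_sl2 + 1)]
    seqs: dict[str, str] = {}

    def hamming(a: str, b: str) -> int:
        return sum(x != y for x, y in zip(a, b))

    for name in names:
        for _ in range(10_000):
            s = list(_random_seq(rng, length))
            s[0:2] = "GG"
            s[10:13] = "CCC"
            cand = "".join(s)
            ok = all(
                hamming(cand, other) >= min_pairwise_dist
                and hamming(cand, revcomp(other)) >= min_pairwise_dist
                for other in seqs.values()
            )
            if ok:
                seqs[name] = cand
                break
        else:  # pragma: no cover
            raise RuntimeError("could not sample a distinct SL sequence")
    return seqs


def _body_is_clean(body: str, repertoire: Repertoire, fold_offset: int,
                   scheme: ScoringScheme) -> bool:
    # no verbatim SL (either strand) anywhere, and no SL detectable in the
    # zero-noise upstream window a hairpin read of this transcript would show
    for seq in repertoire.sequences.values():
        if seq in body or revcomp(seq) in body:
            return False
    window = revcomp(body[:fold_offset + 105])
    return not detect_sl(window, repertoire, scheme, default_threshold)


def generate_reference(config: SimConfig) -> Reference:
    """Build the synthetic transcriptome, gene layout and SL repertoire.

    Operonic genes are placed with 3'-to-start spacing near
    ``sl2_distance_mode``; isolated genes get large gaps.  Raises
    :class:`LayoutError` if a fixed ``contig_len`` cannot hold the layout.
    """
    rng = np.random.default_rng([config.seed, 0])
    scheme = ScoringScheme()
    sls = make_default_repertoire(rng, config.n_sl2_variants, config.sl_length)
    repertoire = Repertoire(dict(sls))

    # block structure: each gene after the first joins the previous block
    # with probability operon_fraction (sharing its strand)
    blocks: list[dict] = []
    for i in range(config.n_genes):
        operonic = i > 0 and rng.random() < config.operon_fraction
        if operonic:
            blocks[-1]["members"].append(i)
        else:
            blocks.append({"strand": "+" if rng.random() < 0.5 else "-",
                           "members": [i]})
    operonic_set = {i for b in blocks for i in b["members"][1:]}

    # endogenous-hairpin genes, preferentially among isolated genes
    n_hp = int(round(config.endogenous_hairpin_fraction * config.n_genes))
    isolated = np.array(sorted(set(range(config.n_genes)) - operonic_set))
    pool = isolated if len(isolated) >= n_hp else np.arange(config.n_genes)
    hairpin_set = set(rng.choice(pool, size=n_hp, replace=False).tolist()) if n_hp else set()

    # transcript bodies (rejection-sampled to be SL-free / detection-free)
    bodies: list[str] = []
    lengths = rng.integers(config.tx_len_range[0], config.tx_len_range[1] + 1,
                           size=config.n_genes)
    d = config.fold_offset
    for i in range(config.n_genes):
        for _ in range(1000):
            body = list(_random_seq(rng, int(lengths[i])))
            if i in hairpin_set:
                # terminal stem: mRNA 5' GG pairs with CC at d-2..d-1
                body[0:2] = "GG"
                body[d - 2:d] = "CC"
            cand = "".join(body)
            if _body_is_clean(cand, repertoire, d, scheme):
                bodies.append(cand)
                break
        else:  # pragma: no cover
            raise RuntimeError("could not sample an SL-free transcript body")

    # genomic layout, left to right
    genes: list[GeneModel] = []
    pos = 1
    first_block = True
    for block in blocks:
        members = block["members"]
        order = members if block["strand"] == "+" else members[::-1]
        if not first_block:
            pos += int(rng.integers(*config.isolated_gap_range))
        first_block = False
        for k, i in enumerate(order):
            if k > 0:
                jit = int(rng.integers(-config.spacing_jitter,
                                       config.spacing_jitter + 1))
                pos += max(1, config.sl2_distance_mode + jit)
            start = pos
            end = start + len(bodies[i]) - 1
            genes.append(GeneModel(
                gene_id=f"gene{i:04d}",
                transcript_id=f"tx{i:04d}",
                contig=config.contig,
                start=start,
                end=end,
                strand=block["strand"],
                kind="hairpin" if i in hairpin_set else "sl",
                operonic=i in operonic_set,
                body=bodies[i],
            ))
            pos = end + 1
    genes.sort(key=lambda g: g.gene_id)
    needed = pos + 500
    if config.contig_len is not None and config.contig_len < needed:
        raise LayoutError(
            f"{config.n_genes} genes need {needed} bp, contig_len={config.contig_len}")
    return Reference(contig=config.contig,
                     contig_len=config.contig_len or needed,
                     genes=genes, sls=sls)


# ---------------------------------------------------------------------------
# read simulation


def _mutate(seq: str, rng: np.random.Generator, err: float,
            sub_frac: float, ins_frac: float, del_frac: float,
            record_ops: bool = False):
    """Apply substitutions/insertions/deletions; optionally record CIGAR ops.

    The op string uses M (consumes ref+read, match or substitution),
    I (read only), D (ref only).
    """
    p_sub, p_ins, p_del = err * sub_frac, err * ins_frac, err * del_frac
    out: list[str] = []
    ops: list[str] = []
    if err > 0:
        u = rng.random(size=(len(seq), 3))
    else:
        u = np.ones((len(seq), 3))
    for i, base in enumerate(seq):
        if u[i, 0] < p_ins:
            out.append(_random_seq(rng, 1))
            ops.append("I")
        if u[i, 1] < p_del:
            ops.append("D")
            continue
        if u[i, 2] < p_sub:
            alts = [b for b in "ACGT" if b != base]
            out.append(alts[int(rng.integers(3))])
        else:
            out.append(base)
        ops.append("M")
    if err > 0 and rng.random() < p_ins:
        out.append(_random_seq(rng, 1))
        ops.append("I")
    return "".join(out), (ops if record_ops else None)


def _compress_cigar(ops: Sequence[str]) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    for op in ops:
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((op, 1))
    return runs


def default_sl_weights(names: Sequence[str]) -> dict[str, float]:
    """Default within-family sampling weights: a skewed SL2 family with two
    dominant variants (SL2.1 ~21%, SL2.8 ~15% of SL2 usage) and the rest
    uniform; SL1 variants uniform."""
    weights = {n: 1.0 for n in names}
    sl2 = [n for n in names if n.startswith("SL2")]
    if "SL2.1" in sl2 and "SL2.8" in sl2 and len(sl2) > 2:
        rest = [n for n in sl2 if n not in ("SL2.1", "SL2.8")]
        weights["SL2.1"] = 0.21
        weights["SL2.8"] = 0.15
        for n in rest:
            weights[n] = 0.64 / len(rest)
    return weights


def _pick_weighted(rng: np.random.Generator, names: list[str],
                   weights: dict[str, float] | None) -> str:
    if not names:
        raise ValueError("empty choice set")
    w = np.array([(weights or {}).get(n, 1.0) for n in names], dtype=float)
    w = w / w.sum()
    return names[int(rng.choice(len(names), p=w))]


def simulate_reads(
    reference: Reference, config: SimConfig, n_reads: int | None = None,
) -> tuple[list[SimRead], list[SimTruthRecord]]:
    """Simulate direct-cDNA reads with per-read truth.

    Each read picks a gene uniformly; trans-spliced genes draw an SL (family
    by operonic status, variant by ``sl_weights``), hairpin genes are always
    ``endogenous_hairpin``.  With probability ``hairpin_artifact_prob`` the
    molecule is a self-primed hairpin cDNA emitted as an antisense read with
    the second-strand copy in its 5' soft-clip; otherwise a conventional
    sense read is emitted.  ``n_reads=0`` yields empty outputs.
    """
    rng = np.random.default_rng([config.seed, 1])
    if n_reads is None:
        n_reads = int(round(config.n_genes * config.reads_per_gene))
    families = reference.repertoire().families
    sl1_names = [n for n, f in families.items() if f == "SL1"]
    sl2_names = [n for n, f in families.items() if f == "SL2"]
    sl_weights = config.sl_weights or default_sl_weights(list(reference.sls))
    reads: list[SimRead] = []
    truths: list[SimTruthRecord] = []
    d = config.fold_offset
    for j in range(n_reads):
        gene = reference.genes[int(rng.integers(len(reference.genes)))]
        if gene.kind == "hairpin":
            true_class, sl_seq, sl_nm = "endogenous_hairpin", "", None
        else:
            p_sl2 = config.operon_sl2_prob if gene.operonic else config.isolated_sl2_prob
            fam2 = rng.random() < p_sl2
            names = sl2_names if (fam2 and sl2_names) else sl1_names
            sl_nm = _pick_weighted(rng, names, sl_weights)
            sl_seq = reference.sls[sl_nm]
            true_class = f"SL:{sl_nm}"
        body = gene.body
        polya = "A" * config.polya_len
        mrna = sl_seq + body + polya
        is_artifact = rng.random() < config.hairpin_artifact_prob

        if is_artifact:
            t = int(rng.integers(config.copy_len_range[0],
                                 config.copy_len_range[1] + 1))
            t = min(t, len(mrna) - d)
            cs = revcomp(mrna[d:d + t])
            stem_nt = min(t, (len(sl_seq) - d) if sl_seq else PROBE_CLIP_NT)
            stem_nt = max(stem_nt, 0)
            seg_copy, seg_stem = cs[:t - stem_nt], cs[t - stem_nt:]
            e2, q2 = config.err_second_strand, config.q_softclip
        else:
            seg_copy = seg_stem = ""
            e2, q2 = config.err_first_strand, config.q_aligned
        e1, q1 = config.err_first_strand, config.q_aligned

        segs = {}
        segs["copy"], _ = _mutate(seg_copy, rng, e2, config.sub_frac,
                                  config.ins_frac, config.del_frac)
        segs["stem"], _ = _mutate(seg_stem, rng, e2, config.sub_frac,
                                  config.ins_frac, config.del_frac)
        segs["sl"], _ = _mutate(sl_seq, rng, e1, config.sub_frac,
                                config.ins_frac, config.del_frac)
        segs["body"], body_ops = _mutate(body, rng, e1, config.sub_frac,
                                         config.ins_frac, config.del_frac,
                                         record_ops=True)
        segs["polya"], _ = _mutate(polya, rng, e1, config.sub_frac,
                                   config.ins_frac, config.del_frac)

        # CIGAR over the body; edge indels are folded into the clips so that
        # soft-clips never contain aligner-recovered bases
        runs = _compress_cigar(body_ops)
        ref_start = 0
        lead_extra = trail_extra = 0
        while runs and runs[0][0] != "M":
            op, ln = runs.pop(0)
            if op == "I":
                lead_extra += ln
            else:
                ref_start += ln
        while runs and runs[-1][0] != "M":
            op, ln = runs.pop()
            if op == "I":
                trail_extra += ln
        seg_order = [segs[n] for n in SEGMENT_NAMES]
        spans: dict[str, tuple[int, int]] = {}
        cursor = 0
        for name, s in zip(SEGMENT_NAMES, seg_order):
            spans[name] = (cursor, cursor + len(s))
            cursor += len(s)
        clip5 = spans["sl"][1] + lead_extra
        clip3 = len(segs["polya"]) + trail_extra
        cigar = f"{clip5}S" if clip5 else ""
        cigar += "".join(f"{ln}{op}" for op, ln in runs)
        cigar += f"{clip3}S" if clip3 else ""

        ref_read = "".join(seg_order)
        qmeans = np.concatenate([
            np.full(len(segs["copy"]) + len(segs["stem"]), q2),
            np.full(len(segs["sl"]) + len(segs["body"]) + len(segs["polya"]), q1),
        ])
        quals = np.clip(np.rint(rng.normal(qmeans, config.q_sd)), 2, 41
                        ).astype(np.int16) if len(qmeans) else np.zeros(0, np.int16)

        read_id = f"read{j:06d}"
        if is_artifact:
            seq_out, quals_out = revcomp(ref_read), quals[::-1].copy()
        else:
            seq_out, quals_out = ref_read, quals
        reads.append(SimRead(read_id=read_id, seq=seq_out, quals=quals_out))
        truths.append(SimTruthRecord(
            read_id=read_id,
            gene_id=gene.gene_id,
            transcript_id=gene.transcript_id,
            true_class=true_class,
            artifact=ARTIFACT_HAIRPIN if is_artifact else ARTIFACT_SENSE,
            is_antisense=is_artifact,
            ref_start=ref_start,
            cigar=cigar,
            clip5_len=clip5,
            clip3_len=clip3,
            spans=spans,
            true_start_offset=ref_start,
        ))
    return reads, truths


# ---------------------------------------------------------------------------
# output writers / oracle alignments


def write_fastq(reads: Iterable[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")


def write_truth(truths: Iterable[SimTruthRecord], path) -> None:
    rows = []
    for t in truths:
        row = {
            "read_id": t.read_id, "gene_id": t.gene_id,
            "transcript_id": t.transcript_id, "true_class": t.true_class,
            "artifact": t.artifact,
            "strand": "-" if t.is_antisense else "+",
            "ref_start": t.ref_start, "cigar": t.cigar,
            "clip5_len": t.clip5_len, "clip3_len": t.clip3_len,
            "true_start_offset": t.true_start_offset,
        }
        for name in SEGMENT_NAMES:
            s, e = t.spans[name]
            row[f"{name}_span"] = f"{s}-{e}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def truth_from_frame(df: pd.DataFrame) -> list[SimTruthRecord]:
    out = []
    for row in df.itertuples(index=False):
        spans = {}
        for name in SEGMENT_NAMES:
            s, e = str(getattr(row, f"{name}_span")).split("-")
            spans[name] = (int(s), int(e))
        out.append(SimTruthRecord(
            read_id=row.read_id, gene_id=row.gene_id,
            transcript_id=row.transcript_id, true_class=row.true_class,
            artifact=row.artifact, is_antisense=row.strand == "-",
            ref_start=int(row.ref_start), cigar=row.cigar,
            clip5_len=int(row.clip5_len), clip3_len=int(row.clip3_len),
            spans=spans, true_start_offset=int(row.true_start_offset),
        ))
    return out


def oracle_alignments(
    reads: Sequence[SimRead], truths: Sequence[SimTruthRecord],
    reference: Reference, out_sam,
) -> None:
    """Write the oracle SAM: one primary record per read, CIGAR from truth.

    Antisense reads get the reverse flag with SEQ/QUAL stored in reference
    orientation (the SAM convention); MAPQ is fixed at 60.  A read without a
    truth record is an error.
    """
    by_id = {t.read_id: t for t in truths}
    tx = reference.transcripts
    names = list(tx)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(tx[n])} for n in names],
    })
    idx = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as fh:
        for r in reads:
            t = by_id.get(r.read_id)
            if t is None:
                raise KeyError(f"no truth record for read {r.read_id}")
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.flag = 16 if t.is_antisense else 0
            a.reference_id = idx[t.transcript_id]
            a.reference_start = t.ref_start
            a.mapping_quality = 60
            a.cigarstring = t.cigar
            if t.is_antisense:
                a.query_sequence = revcomp(r.seq)
                a.query_qualities = list(r.quals[::-1])
            else:
                a.query_sequence = r.seq
                a.query_qualities = list(r.quals)
            fh.write(a)


def emit_oracle_alignments(fastq_path, truth_path, reference: Reference,
                           out_sam) -> None:
    """File-level wrapper: FASTQ + truth TSV -> oracle SAM."""
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        reads.append(SimRead(
            read_id=rec.id, seq=str(rec.seq),
            quals=np.asarray(rec.letter_annotations["phred_quality"],
                             dtype=np.int16)))
    truths = truth_from_frame(read_truth(truth_path))
    oracle_alignments(reads, truths, reference, out_sam)


def simulate_to_dir(config: SimConfig, outdir,
                    n_reads: int | None = None) -> dict[str, Path]:
    """Generate reference + reads + truth + oracle SAM under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = generate_reference(config)
    paths = ref.write(outdir)
    reads, truths = simulate_reads(ref, config, n_reads=n_reads)
    paths["fastq"] = outdir / "reads.fastq"
    paths["truth"] = outdir / "truth.tsv"
    paths["sam"] = outdir / "oracle.sam"
    write_fastq(reads, paths["fastq"])
    write_truth(truths, paths["truth"])
    oracle_alignments(reads, truths, ref, paths["sam"])
    return paths
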
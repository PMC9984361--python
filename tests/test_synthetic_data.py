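"""Simulator contracts: determinism, layout, artifact construction, errors."""

import filecmp

import numpy as np
import pytest

from slclip.gene_summary import Annotation
from slclip.hairpin_detection import revcomp
from slclip.synthetic_data import (
    LayoutError,
    SimConfig,
    generate_reference,
    make_default_repertoire,
    simulate_reads,
    simulate_to_dir,
)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(hairpin_artifact_prob=1.5)
    with pytest.raises(ValueError):
        SimConfig(err_first_strand=0.2, err_second_strand=0.1)
    with pytest.raises(ValueError):
        SimConfig(q_aligned=7, q_softclip=7)
    with pytest.raises(ValueError):
        SimConfig(n_genes=0)


def test_single_gene_reference():
    cfg = SimConfig(seed=3, n_genes=1)
    ref = generate_reference(cfg)
    assert len(ref.genes) == 1
    assert len(ref.transcripts) == 1
    assert set(ref.sls) == {"SL1"} | {f"SL2.{i}" for i in range(1, 12)}


def test_layout_error_when_contig_too_small():
    with pytest.raises(LayoutError):
        generate_reference(SimConfig(seed=3, n_genes=20, contig_len=1000))


def test_repertoire_structure():
    rng = np.random.default_rng(0)
    sls = make_default_repertoire(rng)
    for seq in sls.values():
        assert len(seq) == 22
        assert seq.startswith("GG")
        assert seq[10:13] == "CCC"


def test_operonic_spacing_recoverable_from_gff3(tmp_path):
    cfg = SimConfig(seed=4, n_genes=8, operon_fraction=1.0,
                    sl2_distance_mode=100, spacing_jitter=15)
    ref = generate_reference(cfg)
    paths = ref.write(tmp_path)
    ann = Annotation.from_gff3(paths["annotation"])
    dists = [ann.upstream_distance(g.gene_id) for g in ref.genes]
    measured = [d for d in dists if d is not None]
    assert len(measured) == 7  # all but the first gene of the single operon
    assert all(85 <= d <= 115 for d in measured)


def test_transcripts_contain_no_sl_either_strand():
    ref = generate_reference(SimConfig(seed=5, n_genes=6))
    for body in ref.transcripts.values():
        for sl in ref.sls.values():
            assert sl not in body and revcomp(sl) not in body


def test_zero_noise_softclip_ends_with_exact_sl(zero_noise):
    """At err=0 with artifact probability 1, every trans-spliced read's
    reference-oriented 5' soft-clip ends with the full SL, adjacent to the
    alignment start."""
    checked = 0
    for r in zero_noise.aligned:
        t = zero_noise.truth_by_id[r.read_id]
        if t.sl_name is None:
            continue
        sl = zero_noise.ref.sls[t.sl_name]
        clip = r.seq[: r.clip5_len]
        assert clip.endswith(sl)
        checked += 1
    assert checked > 100


def test_zero_noise_hairpin_clip_is_revcomp_of_transcript_prefix(zero_noise):
    """Endogenous-hairpin reads carry the reverse complement of the
    transcript's fold region at the stem position of the clip."""
    d = zero_noise.cfg.fold_offset
    checked = 0
    for r in zero_noise.aligned:
        t = zero_noise.truth_by_id[r.read_id]
        if t.true_class != "endogenous_hairpin":
            continue
        body = zero_noise.ref.transcripts[t.transcript_id]
        clip = r.seq[: r.clip5_len]
        assert clip[-13:] == revcomp(body[d : d + 13])
        checked += 1
    assert checked > 50


def test_antisense_fraction_tracks_artifact_probability(tmp_path):
    cfg = SimConfig(seed=6, n_genes=5, hairpin_artifact_prob=0.95,
                    err_first_strand=0.0, err_second_strand=0.0)
    ref = generate_reference(cfg)
    n = 4000
    _, truths = simulate_reads(ref, cfg, n_reads=n)
    frac = sum(t.is_antisense for t in truths) / n
    sd = np.sqrt(0.95 * 0.05 / n)
    assert abs(frac - 0.95) <= 3 * sd


def test_sense_reads_have_short_clips(tmp_path):
    cfg = SimConfig(seed=7, n_genes=5, hairpin_artifact_prob=0.0,
                    err_first_strand=0.0, err_second_strand=0.0)
    ref = generate_reference(cfg)
    _, truths = simulate_reads(ref, cfg, n_reads=200)
    for t in truths:
        assert not t.is_antisense
        assert t.clip5_len <= max(len(s) for s in ref.sls.values())


def test_zero_reads_yield_empty_outputs():
    cfg = SimConfig(seed=8, n_genes=2)
    ref = generate_reference(cfg)
    reads, truths = simulate_reads(ref, cfg, n_reads=0)
    assert reads == [] and truths == []


def test_oracle_cigar_round_trip_at_zero_noise(zero_noise):
    """Soft-clip lengths seen through the SAM parser equal the truth."""
    for r in zero_noise.aligned:
        t = zero_noise.truth_by_id[r.read_id]
        assert r.clip5_len == t.clip5_len
        assert r.clip3_len == t.clip3_len
        assert r.is_antisense == t.is_antisense
        assert r.ref_start == t.ref_start


def test_truth_spans_tile_each_read(zero_noise, noisy):
    for run in (zero_noise, noisy):
        for t in run.truths[:300]:
            spans = [t.spans[n] for n in ("copy", "stem", "sl", "body", "polya")]
            cursor = 0
            for s, e in spans:
                assert s == cursor and e >= s
                cursor = e
            read = next(r for r in run.reads if r.read_id == t.read_id)
            assert cursor == len(read.seq)


def test_softclip_qualities_lower_than_aligned(zero_noise):
    clip_q, aligned_q = [], []
    for r in zero_noise.aligned[:300]:
        if r.clip5_len > 50:
            clip_q.append(np.mean(r.quals[: r.clip5_len - 30]))
            aligned_q.append(np.mean(r.quals[r.clip5_len : r.clip5_len + 200]))
    assert np.mean(clip_q) < np.mean(aligned_q)


def test_emit_oracle_alignments_from_files_matches_in_memory(tmp_path):
    cfg = SimConfig(seed=10, n_genes=3)
    paths = simulate_to_dir(cfg, tmp_path / "sim", n_reads=40)
    from slclip.synthetic_data import emit_oracle_alignments

    ref = generate_reference(cfg)
    out = tmp_path / "roundtrip.sam"
    emit_oracle_alignments(paths["fastq"], paths["truth"], ref, out)
    assert out.read_text() == (tmp_path / "sim" / "oracle.sam").read_text()


def test_emit_oracle_alignments_requires_truth(tmp_path):
    cfg = SimConfig(seed=10, n_genes=3)
    ref = generate_reference(cfg)
    reads, truths = simulate_reads(ref, cfg, n_reads=5)
    from slclip.synthetic_data import oracle_alignments

    with pytest.raises(KeyError):
        oracle_alignments(reads, truths[:-1], ref, tmp_path / "x.sam")


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = SimConfig(seed=9, n_genes=3)
    a = simulate_to_dir(cfg, tmp_path / "a", n_reads=60)
    b = simulate_to_dir(cfg, tmp_path / "b", n_reads=60)
    for key in a:
        assert filecmp.cmp(a[key], b[key], shallow=False), key
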
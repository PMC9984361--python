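from types import SimpleNamespace

import pytest

from slclip.alignment_io import load_alignments
from slclip.synthetic_data import (
    SimConfig,
    generate_reference,
    oracle_alignments,
    simulate_reads,
)


def _run(cfg: SimConfig, n_reads: int, tmpdir) -> SimpleNamespace:
    ref = generate_reference(cfg)
    reads, truths = simulate_reads(ref, cfg, n_reads=n_reads)
    sam = tmpdir / "oracle.sam"
    oracle_alignments(reads, truths, ref, sam)
    return SimpleNamespace(
        cfg=cfg, ref=ref, reads=reads, truths=truths, sam=sam,
        truth_by_id={t.read_id: t for t in truths},
        aligned=list(load_alignments(sam)),
    )


@pytest.fixture(scope="session")
def zero_noise(tmp_path_factory):
    """Error-free hairpin-cDNA library over 10 genes (SL1/SL2/hairpin mix)."""
    cfg = SimConfig(
        seed=11, n_genes=10, endogenous_hairpin_fraction=0.3,
        operon_fraction=0.3, err_first_strand=0.0, err_second_strand=0.0,
        hairpin_artifact_prob=1.0,
    )
    return _run(cfg, 2000, tmp_path_factory.mktemp("zero_noise"))


@pytest.fixture(scope="session")
def noisy(tmp_path_factory):
    """Nanopore-like noise: 5% first-strand / 15% second-strand error."""
    cfg = SimConfig(
        seed=12, n_genes=20, endogenous_hairpin_fraction=0.3,
        operon_fraction=0.3, err_first_strand=0.05, err_second_strand=0.15,
        hairpin_artifact_prob=1.0,
    )
    return _run(cfg, 2000, tmp_path_factory.mktemp("noisy"))
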
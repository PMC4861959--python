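import numpy as np
import pandas as pd
import pytest

from rbpregulon.formats import ExpressionMatrix, Peak, TranscriptRecord
from rbpregulon.network import TargetNetwork
from rbpregulon.synth import GeneratorConfig, generate


@pytest.fixture
def simple_transcript():
    """Two-exon + strand transcript on chr1 spanning [1000, 2000)."""
    return TranscriptRecord(
        "T1", "G1", "protein_coding", "chr1", "+", ((1000, 1200), (1800, 2000))
    )


@pytest.fixture
def tiny_annotation():
    return [
        TranscriptRecord("T1", "G1", "protein_coding", "chr1", "+", ((1000, 1200),)),
        TranscriptRecord("T2", "G1", "lincRNA", "chr1", "+", ((5000, 5300),)),
        TranscriptRecord("T3", "G2", "protein_coding", "chr2", "-", ((100, 400),)),
    ]


@pytest.fixture
def tiny_expression():
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.uniform(1, 100, size=(3, 5)),
        index=["T1", "T2", "T3"],
        columns=[f"t{i}" for i in range(5)],
    )
    return ExpressionMatrix(data)


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort shared across tests (12 RBPs, 600 transcripts)."""
    cfg = GeneratorConfig(
        seed=5, n_rbps=12, n_transcripts=600, targets_per_rbp=(30, 40),
        n_multi_tx_genes=10, decoys_per_rbp=10,
    )
    return generate(cfg)


def brute_force_targets(peaks, transcripts, flank=300):
    """O(n*m) reference for peak-to-target mapping: a transcript is a target
    iff some peak shares >=1 base with some +/-flank exon-boundary window."""
    net = TargetNetwork()
    for p in peaks:
        net.targets.setdefault(p.rbp_id, set())
        for t in transcripts:
            if t.chrom != p.chrom:
                continue
            hit = False
            for s, e in t.exons:
                for b in (s, e - 1):
                    lo, hi = max(0, b - flank), b + flank + 1
                    if p.start < hi and p.end > lo:
                        hit = True
            if hit:
                net.targets[p.rbp_id].add(t.transcript_id)
    return net


def random_instance(rng, n_peaks=50, n_tx=20):
    """Random peaks + transcripts for oracle comparisons."""
    chroms = ["c1", "c2"]
    txs = []
    for i in range(int(rng.integers(1, n_tx + 1))):
        n_ex = int(rng.integers(1, 4))
        pos = int(rng.integers(0, 5000))
        exons = []
        for _ in range(n_ex):
            length = int(rng.integers(50, 400))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(50, 800))
        txs.append(
            TranscriptRecord(
                f"T{i}", f"G{i}", "protein_coding",
                chroms[int(rng.integers(2))], "+", tuple(exons),
            )
        )
    peaks = [
        Peak(
            f"R{int(rng.integers(3))}",
            chroms[int(rng.integers(2))],
            s := int(rng.integers(0, 9000)),
            s + int(rng.integers(10, 200)),
            ".",
            0.01,
        )
        for _ in range(int(rng.integers(1, n_peaks + 1)))
    ]
    return peaks, txs
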
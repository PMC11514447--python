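"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from posclip.transcriptome import REGIONS, TranscriptModel


def make_model(utr5=200, cds=300, utr3=400, n_exons=1, strand="+",
               chrom="chr1", start=1000, gene_id="g", rng=None):
    """Build a transcript model with the requested UTR/CDS geometry and a
    random (or even) exon split."""
    length = utr5 + cds + utr3
    if rng is None:
        cuts = np.linspace(0, length, n_exons + 1).astype(int)[1:-1]
    else:
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_exons - 1,
                                  replace=False)) if n_exons > 1 else np.array([], int)
    sizes = np.diff(np.concatenate([[0], cuts, [length]]))
    exons, g = [], start
    intron = 137
    for sz in sizes:
        exons.append((g, g + int(sz)))
        g += int(sz) + intron
        intron += 61  # vary intron sizes
    return TranscriptModel(gene_id, f"{gene_id}.t1", chrom, strand,
                           tuple(exons), utr5, utr5 + cds)


def random_model(rng, gene_id="g"):
    utr5 = int(rng.integers(1, 400))
    cds = int(rng.integers(3, 1200))
    utr3 = int(rng.integers(1, 600))
    n_exons = int(rng.integers(1, 5))
    n_exons = min(n_exons, utr5 + cds + utr3)
    strand = "+" if rng.random() < 0.5 else "-"
    return make_model(utr5, cds, utr3, n_exons, strand,
                      start=int(rng.integers(0, 5000)), gene_id=gene_id, rng=rng)


def spliced_positions(model):
    """Brute-force enumeration of genomic positions in transcript order:
    concatenate exon bases 5'->3' (reverse order for minus strand)."""
    out = []
    for s, e in model.exons:
        out.extend(range(s, e))
    if model.strand == "-":
        out = out[::-1]
    return out


def region_oracle(model, window=50):
    """Literal materialization of the five regions as interval sets, with
    the truncation and short-CDS tie rules applied position by position."""
    L = model.length
    a1, a2 = model.cds_start_tx, model.cds_end_tx
    labels = []
    for pos in range(L):
        in_start = a1 - window <= pos < a1 + window
        in_stop = a2 - window <= pos < a2 + window
        if in_start and in_stop:
            labels.append("start" if abs(pos - a1) < abs(pos - a2) else "stop")
        elif in_start:
            labels.append("start")
        elif in_stop:
            labels.append("stop")
        elif pos < a1 - window:
            labels.append("five_prime_utr")
        elif pos >= a2 + window:
            labels.append("three_prime_utr")
        else:
            labels.append("cds")
    return labels


@pytest.fixture
def toy_models():
    return {
        "gA": make_model(200, 300, 400, n_exons=1, gene_id="gA"),
        "gB": make_model(10, 300, 540, n_exons=2, gene_id="gB", start=5000),
        "gC": make_model(120, 60, 200, n_exons=3, gene_id="gC", strand="-",
                         start=9000),
    }


assert set(REGIONS) == {
    "five_prime_utr", "start", "cds", "stop", "three_prime_utr"
}
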
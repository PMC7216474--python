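import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sjkit.formats import AnnotationSet, GenomeAccessor, TranscriptModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def tm(tid, exons, strand="+", gene="g1", chrom="chr1"):
    """Shorthand transcript constructor used throughout the tests."""
    return TranscriptModel.from_coords(tid, gene, chrom, strand, exons)


@pytest.fixture
def toy_annotation():
    """One 4-exon gene (the workhorse reference locus) plus a mono-exon gene."""
    t1 = tm("t1", [(100, 200), (300, 400), (500, 600), (700, 800)])
    t2 = tm("m1", [(2000, 2500)], gene="g2")
    return AnnotationSet(genes={"g1": [t1], "g2": [t2]})


@pytest.fixture
def random_toy_genes():
    """Factory: random single-gene transcript sets for oracle comparisons.

    Each gene has <= 5 exons and <= 4 isoforms derived from a base
    structure by skipping exons, retaining introns, shifting boundaries
    and truncating — all structurally valid by construction.
    """

    def make(seed, n_genes):
        rng = np.random.default_rng(seed)
        genes = []
        for g in range(n_genes):
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            n_ex = int(rng.integers(3, 6))
            pos = int(rng.integers(0, 1000))
            exons = []
            for _ in range(n_ex):
                ex_len = int(rng.integers(30, 120))
                exons.append((pos, pos + ex_len))
                pos += ex_len + int(rng.integers(40, 200))
            base = exons
            txs = []
            n_iso = int(rng.integers(2, 5))
            for k in range(n_iso):
                ex = [list(e) for e in base]
                op = rng.integers(0, 5)
                if op == 0 and len(ex) >= 3:  # skip an internal exon
                    del ex[int(rng.integers(1, len(ex) - 1))]
                elif op == 1 and len(ex) >= 2:  # retain an intron
                    i = int(rng.integers(0, len(ex) - 1))
                    ex[i][1] = ex[i + 1][1]
                    del ex[i + 1]
                elif op == 2 and len(ex) >= 2:  # shift a boundary
                    i = int(rng.integers(0, len(ex) - 1))
                    delta = int(rng.integers(1, 4)) * 6
                    if ex[i + 1][0] - ex[i][1] > delta + 8:
                        if rng.integers(0, 2) == 0:
                            ex[i][1] += delta
                        else:
                            ex[i + 1][0] -= delta
                elif op == 3 and len(ex) >= 3:  # truncate a terminal exon
                    if rng.integers(0, 2) == 0:
                        del ex[0]
                    else:
                        del ex[-1]
                # op == 4: keep the base structure (duplicate chain)
                txs.append(
                    TranscriptModel.from_coords(
                        f"g{g}.t{k}", f"g{g}", "chrT", strand,
                        [tuple(e) for e in ex],
                    )
                )
            genes.append(txs)
        return genes

    return make


@pytest.fixture
def flat_genome():
    """A featureless genome long enough for the toy annotation."""
    return GenomeAccessor({"chr1": "A" * 3000})
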
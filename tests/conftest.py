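import numpy as np
import pandas as pd
import pytest

from genesig.containers import ExpressionMatrix, GeneAnnotationSet, SubtypeLabels
from genesig.preprocess import drop_constant_genes, max_normalize
from genesig.simulate import SimSpec, gen_expression, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 200 x 500 four-subtype cohort with survival and IHC."""
    return simulate_cohort(SimSpec(seed=7))


@pytest.fixture(scope="session")
def blobs():
    """Well-separated 4-class data with two private informative genes per
    class among 50 total genes; cheap enough for repeated fits."""
    spec = SimSpec(
        n_samples=120,
        n_genes=50,
        n_informative_per_class=3,
        effect_size=6.0,
        seed=3,
    )
    matrix, labels, annotation, truth = gen_expression(spec)
    norm = max_normalize(drop_constant_genes(matrix))
    return {
        "X": norm.X(),
        "y": labels.y(norm.sample_ids),
        "genes": norm.gene_ids,
        "truth": truth,
        "matrix": norm,
    }


@pytest.fixture()
def toy_expression(tmp_path):
    """3-gene x 2-sample TSV on disk."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene_id\tS1\tS2\n"
        "G1\t1.0\t2.0\n"
        "G2\t0.5\t0.25\n"
        "G3\t3.0\t4.0\n"
    )
    return path


def make_annotation(records):
    rows = []
    for gene_id, biotype, length in records:
        rows.append(
            {
                "gene_id": gene_id,
                "biotype": biotype,
                "chrom": "chr1",
                "start": 1000,
                "end": 1000 + length - 1,
                "length_bp": length,
                "is_coding": biotype == "protein_coding",
            }
        )
    return GeneAnnotationSet(pd.DataFrame(rows))


def make_matrix(gene_ids, n_samples=4, seed=0):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        rng.uniform(0.5, 2.0, size=(len(gene_ids), n_samples)),
        index=gene_ids,
        columns=[f"S{i}" for i in range(n_samples)],
    )
    return ExpressionMatrix(data)
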
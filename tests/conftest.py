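import numpy as np
import pytest

from sagescape.layout import LibraryLayout
from sagescape import synthetic_data as sim


@pytest.fixture
def layout():
    return LibraryLayout()


@pytest.fixture
def small_sim(layout):
    """50 transcripts, 2 tissues x 2 reps, 500 error-free reads per sample."""
    records, tag_of = sim.simulate_transcriptome(50, seed=11, layout=layout)
    tissues = ["LIV", "MSC"]
    sheet = sim.make_sample_sheet(tissues, 2, barcode_len=layout.barcode_len, seed=11)
    design = sim.block_design(2, tissues)
    expr, cluster_of, tissue_of = sim.simulate_expression(
        [r[0] for r in records], design, tissues, 2, seed=11
    )
    reads = sim.simulate_reads(expr, tag_of, sheet, layout, depth=500, error_rate=0.0, seed=11)
    return {
        "records": records,
        "tag_of": tag_of,
        "sheet": sheet,
        "expr": expr,
        "cluster_of": cluster_of,
        "tissue_of": tissue_of,
        "reads": reads,
    }


def reads_to_records(reads):
    from sagescape.extract import ReadRecord

    return [ReadRecord(rid, seq, [ord(c) - 33 for c in qual]) for rid, seq, qual in reads]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
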
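import numpy as np
import pytest

from neutralcomm.core_io import CountTable, SampleMetadata, TaxonomyMap, parse_lineage


@pytest.fixture
def toy_table() -> CountTable:
    """3 samples x 4 OTUs with hand-checkable totals."""
    counts = np.array(
        [
            [10, 0, 5, 1],
            [0, 20, 5, 0],
            [30, 10, 0, 0],
        ]
    )
    return CountTable(["s1", "s2", "s3"], ["o1", "o2", "o3", "o4"], counts)


@pytest.fixture
def toy_taxonomy() -> TaxonomyMap:
    return TaxonomyMap(
        {
            "o1": parse_lineage("k__Bacteria; p__Proteobacteria; c__Alpha; o__Rick; f__F1; g__G1"),
            "o2": parse_lineage("k__Bacteria; p__Proteobacteria; c__Gamma; o__Ent; f__F2; g__G2"),
            "o3": parse_lineage("k__Bacteria; p__Firmicutes"),
            "o4": parse_lineage("k__Bacteria"),
        }
    )


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    return SampleMetadata(
        {
            "s1": {"species": "A", "location": "north"},
            "s2": {"species": "A", "location": "south"},
            "s3": {"species": "B", "location": "north"},
        }
    )


@pytest.fixture
def classic_tsv(tmp_path):
    path = tmp_path / "table.tsv"
    path.write_text(
        "# Constructed from biom file\n"
        "#OTU ID\ts1\ts2\ttaxonomy\n"
        "o1\t4\t0\tk__Bacteria; p__Proteobacteria\n"
        "o2\t1\t2\tk__Bacteria; p__Firmicutes\n"
        "o3\t0\t7\t\n"
    )
    return path
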
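import pytest

from startscan.sequence_io import GeneRecord, GeneSet


def gene(gene_id: str, utr5: str, orf: str, utr3: str = "") -> GeneRecord:
    return GeneRecord(gene_id, utr5, orf, utr3)


def geneset(*genes: GeneRecord, min_utr_len: int = 6) -> GeneSet:
    return GeneSet(genes, min_utr_len=min_utr_len)


@pytest.fixture
def toy_genes() -> GeneSet:
    """Three small hand-checkable genes."""
    return geneset(
        gene("gA", "ATGCAT", "ATGATGTAA"),
        gene("gB", "CCCCCC", "ATGAAATAA"),
        gene("gC", "ACGTAG", "ATGAAACCCGGGTAA"),
    )
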
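import pytest

from phylodiv import datasets


@pytest.fixture(scope="session")
def rooted_example():
    """The five-taxon weighted hierarchy (total weight 25)."""
    return datasets.example_cluster_weighting()


@pytest.fixture(scope="session")
def unrooted_example():
    """The matching seven-split weighting (total weight 25)."""
    return datasets.example_split_weighting()
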
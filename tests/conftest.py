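import pandas as pd
import pytest

from temark.annotation import TETypeCatalog
from temark.synthetic import SyntheticGenomeSpec, TETypeSpec, generate_te_annotation

TOY_SIZES = {"chrA": 1_200_000, "chrB": 800_000}


@pytest.fixture(scope="session")
def toy_sizes():
    return dict(TOY_SIZES)


@pytest.fixture(scope="session")
def toy_spec():
    return SyntheticGenomeSpec(
        chrom_sizes=dict(TOY_SIZES),
        te_types=[
            TETypeSpec("alpha", "LINE", 60, (300, 900), 50.0),
            TETypeSpec("beta", "SINE", 60, (300, 500), 150.0),
            TETypeSpec("gamma", "LTR", 60, (400, 800), 80.0),
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_catalog(toy_spec):
    return generate_te_annotation(toy_spec)


def make_catalog(rows):
    """Catalog from (chrom, start, end, strand, type_name, te_class) rows."""
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "type_name", "te_class"]
    )
    df["te_family"] = df["te_class"]
    df["millidiv"] = 0.0
    return TETypeCatalog(df)
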
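import numpy as np
import pandas as pd
import pytest

from barseq_popdyn.barcode_quant import CountTable, SampleMeta


@pytest.fixture
def make_count_table():
    """Build a CountTable from {sample_id: (condition, time_h, {gene: count})}."""

    def build(spec, vessel="bioreactor"):
        rows = []
        for sid, (condition, time_h, counts) in spec.items():
            rows.append(
                (SampleMeta(sid, condition, vessel, time_h), counts)
            )
        return CountTable.from_samples(rows)

    return build


@pytest.fixture
def catalog_tsv(tmp_path):
    """Write a catalog TSV from (barcode, gene) rows; returns the path."""

    def write(rows, header="barcode\tgene"):
        path = tmp_path / "catalog.tsv"
        lines = [header] + ["\t".join(r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return write


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def random_abundance_frame(rng):
    """Random compositional tables for oracle-equivalence checks."""

    def make(n_samples, n_genes, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        X = local.dirichlet(np.ones(n_genes) * 0.5, size=n_samples)
        return pd.DataFrame(
            X,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"g{j}" for j in range(n_genes)],
        )

    return make
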
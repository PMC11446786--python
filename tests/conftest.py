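import numpy as np
import pandas as pd
import pytest

from irpipe.containers import IRCountTable


def make_table(inclusion, skipping, groups, li=1, ls=1, gene_symbols=None):
    """Build a small IRCountTable from raw arrays.

    ``groups`` is a list of (label, n_samples); columns are laid out group by
    group in order.
    """
    inclusion = np.atleast_2d(np.asarray(inclusion))
    skipping = np.atleast_2d(np.asarray(skipping))
    n_events = inclusion.shape[0]
    event_ids = [f"EV{i + 1:04d}" for i in range(n_events)]
    if gene_symbols is None:
        gene_symbols = [f"GENE{i + 1:04d}" for i in range(n_events)]
    events = pd.DataFrame(
        {
            "gene_id": gene_symbols,
            "gene_symbol": gene_symbols,
            "chrom": "chr1",
            "strand": "+",
            "intron_start": np.arange(n_events) * 100,
            "intron_end": np.arange(n_events) * 100 + 50,
            "inclusion_form_len": li,
            "skip_form_len": ls,
        },
        index=pd.Index(event_ids, name="event_id"),
    )
    sample_ids, sample_groups = [], []
    for label, n in groups:
        for j in range(n):
            sample_ids.append(f"{label}_{j + 1}")
            sample_groups.append(label)
    samples = pd.Series(sample_groups, index=pd.Index(sample_ids, name="sample_id"), name="group")
    return IRCountTable(
        events=events,
        samples=samples,
        inclusion=pd.DataFrame(inclusion, index=events.index, columns=sample_ids),
        skipping=pd.DataFrame(skipping, index=events.index, columns=sample_ids),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
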
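"""Bundled example data."""

from importlib import resources

import pandas as pd

__all__ = ["load_vat_da_proteins"]


def load_vat_da_proteins() -> pd.DataFrame:
    """Reported differential-abundance summary from a published label-free
    proteomic comparison of visceral adipose tissue between type 2 diabetic
    (DM) and non-diabetic (NDM) subjects (10 per group, 50 imputation
    rounds).

    Columns: UniProt ``accession``, ``gene`` symbol, ``fold_change``
    (DM/NDM, linear scale), ``q_value`` (median FDR-adjusted significance),
    and ``pass_rate`` (fraction of imputation rounds with q < 0.1).  Useful
    as a worked example for the stability-call and direction rules.
    """
    ref = resources.files("lfqstab").joinpath("data/vat_da_proteins.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
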
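"""Bundled reference data: the published ranked table of 97 anti-correlated
mRNA–miRNA pairs (responders vs non-responders), as printed."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .integration import PairResult


def load_pair_table() -> pd.DataFrame:
    """The 97-row published pair table as a DataFrame, print precision."""
    ref = resources.files("mirpair").joinpath("data/table4_pairs.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_pairs() -> list[PairResult]:
    """The published pair table as :class:`PairResult` records, in rank order."""
    df = load_pair_table()
    return [
        PairResult(
            mirna_id=row["Mature miRNA"],
            mrna_id=row["mRNA"],
            cor=row["cor"],
            p_value=row["p-value"],
            adj_p=row["adj.p-value"],
            logratio_mirna=row["logratio.miRNA"],
            logratio_mrna=row["logratio.mRNA"],
            mean_exp_mirna=row["meanExp.miRNA"],
            mean_exp_mrna=row["meanExp.mRNA"],
            s_score=row["S score"],
            fc_mirna=row["FC.miRNA (R vs NR)"],
            fc_mrna=row["FC.mRNA (R vs NR)"],
        )
        for _, row in df.iterrows()
    ]
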
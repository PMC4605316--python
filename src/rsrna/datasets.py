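"""Bundled example datasets.

``load_qpcr_panel`` returns the qPCR validation panel shipped with the
package: raw Ct values for nine rsRNA:target pairs measured across four
cancer cell lines (A549, MDA-MB-231, HeLa, MCF7), together with the
anti-correlation coefficients reported for them. Ct is inversely related
to abundance, so a repressive sRNA:target relation appears as a negative
Pearson correlation between the two Ct profiles.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io as rio


def _data_path(name: str):
    return resources.files("rsrna").joinpath("data", name)


def load_qpcr_panel() -> tuple[pd.DataFrame, list[tuple[str, str]], dict[tuple[str, str], float]]:
    """Return (ct_table, pairs, reported_pcc).

    ``ct_table`` is entities x cell lines with explicit NA; ``pairs`` lists
    the (rsRNA, gene) combinations assayed; ``reported_pcc`` maps each pair
    to the originally reported 2-decimal correlation coefficient.
    """
    with resources.as_file(_data_path("qpcr_panel_ct.tsv")) as path:
        ct = rio.read_ct_table(path)
    with resources.as_file(_data_path("qpcr_panel_pairs.tsv")) as path:
        pairs_df = rio.read_table(path, required=["srna_id", "gene_id", "reported_pcc"])
    pairs = [(str(r.srna_id), str(r.gene_id)) for r in pairs_df.itertuples()]
    reported = {
        (str(r.srna_id), str(r.gene_id)): float(r.reported_pcc) for r in pairs_df.itertuples()
    }
    return ct, pairs, reported
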
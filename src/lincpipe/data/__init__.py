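"""Bundled reference tables.

``del_deptg_tallies.tsv`` holds the published per-DEL direction tallies from
the Yorkshire vs Wannanhua longissimus dorsi comparison: for each of the 16
differentially expressed lincRNAs with trans targets, the number of
differentially expressed potential target genes and how many of them move
with ("up") versus against ("down") the lincRNA. Used as a worked example
for the network tally operations.
"""

from importlib import resources

import pandas as pd

from ..targets import DirectionTally


def load_published_tallies() -> list:
    """The 16 published (DEL, DEPTGs, up, down) rows as DirectionTally objects."""
    with resources.files(__package__).joinpath("del_deptg_tallies.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        DirectionTally(r.lincRNA_id, int(r.n_deptg), int(r.n_up), int(r.n_down))
        for r in df.itertuples()
    ]
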
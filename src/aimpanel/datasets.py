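"""Packaged datasets.

The package ships the 48-SNP continental AIM panel: rs numbers, alleles,
map positions and ancestral-allele frequencies in the four continental
reference groups (African, American, European, East Asian), pooled over
25 CEPH-HGDP training populations, together with the groups' diploid
sample sizes (97, 57, 158 and 177).
"""

from __future__ import annotations

from importlib import resources

from .containers import FrequencyTable
from .io_formats import read_frequency_table

__all__ = ["table2_fixture", "CONTINENTAL_GROUPS"]

CONTINENTAL_GROUPS = ("African", "American", "European", "East Asian")


def table2_fixture() -> FrequencyTable:
    """The packaged 48 x 4 continental AIM frequency table."""
    path = resources.files("aimpanel.data").joinpath("table2_aims.tsv")
    with resources.as_file(path) as p:
        return read_frequency_table(p)
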
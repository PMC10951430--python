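"""Normalization of heterogeneous biotype labels to a small set of classes.

Annotation databases disagree on biotype vocabulary (``lncRNA`` vs ``lnc_RNA``
vs ``lincRNA`` ...), so the merge and all downstream per-class statistics run
on a normalized class: pcg, lncRNA, miRNA, other_small_rna or other.  The
mapping ships as an editable table so any source dialect can be accommodated.
"""

from __future__ import annotations

from .models import LNCRNA, MIRNA, OTHER, OTHER_SMALL_RNA, PCG

#: default raw-biotype -> class table; unknown labels map to ``other``.
DEFAULT_BIOTYPE_TABLE: dict[str, str] = {
    "protein_coding": PCG,
    "lncRNA": LNCRNA,
    "lincRNA": LNCRNA,
    "lnc_RNA": LNCRNA,
    "antisense": LNCRNA,
    "miRNA": MIRNA,
    "snoRNA": OTHER_SMALL_RNA,
    "snRNA": OTHER_SMALL_RNA,
    "tRNA": OTHER_SMALL_RNA,
    "rRNA": OTHER_SMALL_RNA,
    # identity on the normalized labels themselves, so the mapping is
    # idempotent and round-trips through written GTFs
    PCG: PCG,
    MIRNA: MIRNA,
    OTHER_SMALL_RNA: OTHER_SMALL_RNA,
    OTHER: OTHER,
}


def normalize_biotype(raw_biotype: str, table: dict[str, str] | None = None) -> str:
    """Map a raw biotype label to its normalized class (total, never raises)."""
    if table is None:
        table = DEFAULT_BIOTYPE_TABLE
    return table.get(raw_biotype, OTHER)


def load_biotype_table(path: str) -> dict[str, str]:
    """Read a two-column TSV (raw_biotype <TAB> class) into a mapping.

    Lines starting with '#' are comments.  The normalized labels are always
    present as identities so the result stays idempotent.
    """
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            raw, cls = line.split("\t")[:2]
            table[raw] = cls
    for cls in (PCG, LNCRNA, MIRNA, OTHER_SMALL_RNA, OTHER):
        table.setdefault(cls, cls)
    return table
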
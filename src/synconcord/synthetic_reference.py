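"""Synthetic stand-in reference lists with the study's published counts.

The underlying gene lists (the 63 up-regulated synaptosomal proteins and the
793-protein Shank3 interactome) are not publicly deposited, so these
functions build deterministic synthetic stand-ins that reproduce the
published summary counts exactly: a 63-identifier up-regulated list
containing six ribosomal-protein symbols and Shank3, and a 793-identifier
interactome sharing exactly eight identifiers (including Shank3) with it —
an overlap of 12.7% of the up-regulated list. They validate the overlap and
tagging machinery against the printed counts; they are NOT the published
membership, and any real analysis must supply the genuine lists.
"""

from __future__ import annotations

#: Six ribosomal-protein symbols in the synthetic up-regulated list. RPLP1
#: and RPL36A are the two validated members; the remaining four (incl. one
#: mitochondrial RP) complete the published count of six.
SYNTHETIC_UP_RIBOSOMAL = ("rplp1", "rpl36a", "rpl22l1", "rps19", "rps2", "mrpl4")

#: Eight identifiers shared between the synthetic lists: Shank3 itself plus
#: seven postsynaptic-density proteins plausible in both an up-regulated
#: synaptosomal proteome and a Shank3 interactome.
SYNTHETIC_SHARED = (
    "shank3",
    "homer1",
    "dlgap1",
    "dlg4",
    "camk2a",
    "syngap1",
    "grin2b",
    "shank1",
)


def synthetic_upregulated_proteins() -> list[str]:
    """Synthetic 63-identifier up-regulated synaptosomal protein list.

    Contains the eight interactome-shared identifiers (incl. shank3), the
    six ribosomal-protein symbols, and 49 generic filler symbols.
    """
    n_filler = 63 - len(SYNTHETIC_SHARED) - len(SYNTHETIC_UP_RIBOSOMAL)
    filler = [f"upsyn{i:02d}" for i in range(1, n_filler + 1)]
    return list(SYNTHETIC_SHARED) + list(SYNTHETIC_UP_RIBOSOMAL) + filler


def synthetic_shank3_interactome() -> list[str]:
    """Synthetic 793-identifier scaffold interactome list.

    Shares exactly the eight :data:`SYNTHETIC_SHARED` identifiers with
    :func:`synthetic_upregulated_proteins`; the remaining 785 are generic
    filler symbols disjoint from the up-regulated list.
    """
    n_filler = 793 - len(SYNTHETIC_SHARED)
    filler = [f"psdint{i:03d}" for i in range(1, n_filler + 1)]
    return list(SYNTHETIC_SHARED) + filler
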
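"""Small curated fixtures shipped with the package.

* :func:`pca_mirnas` — the 15 mature maize miRNAs predicted to hybridize with
  prostate-cancer pathway mRNAs (15 identifiers over 11 distinct sequences;
  several family members share a mature sequence).  miRBase carries no read
  counts, so these records have ``read_count=None``.
* :func:`pca_interactions` — the curated set of predicted maize-miRNA
  interaction sites with prostate-cancer pathway genes (14 sites over 13
  genes: one gene is hit at two positions), as (gene, region, MFE) rows.  The
  contributing miRNA identities are not part of this fixture; synthetic
  transcript ids are assigned per row so gene-level deduplication is
  exercised faithfully.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotate import Interaction
from .io_formats import MatureMiRNA


def _data_path(name: str):
    return resources.files("xkmir.data").joinpath(name)


def pca_mirnas() -> list[MatureMiRNA]:
    with resources.as_file(_data_path("zma_pca_mirnas.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    return [
        MatureMiRNA(mirna_id=r.mirna_id, species=r.species, sequence=r.sequence)
        for r in df.itertuples(index=False)
    ]


def pca_interactions() -> list[Interaction]:
    with resources.as_file(_data_path("pca_interactions.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    out = []
    seen: dict[str, int] = {}
    for r in df.itertuples(index=False):
        k = seen.get(r.gene_symbol, 0) + 1
        seen[r.gene_symbol] = k
        out.append(
            Interaction(
                mirna_id="zma-miR-unassigned",
                transcript_id=f"{r.gene_symbol}.t{k}",
                gene_symbol=r.gene_symbol,
                region=r.region,
                site_start=0,
                mfe=float(r.mfe),
            )
        )
    return out
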
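"""Packaged worked-example tables for nine PRMT1 circRNAs.

Two tables from the PRMT1 circRNA study are shipped with the package as
plain TSV: the catalog of the nine discovered circRNAs (accessions
ON081037-ON081045, exon composition with truncation asterisks, lengths) and
the two top-scoring predicted sponged miRNAs per circRNA with their binding
motifs.  They serve as ground-truth inputs for the reporting layer and for
end-to-end checks that do not require the deposited sequences.
"""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

__all__ = [
    "load_table1",
    "load_table2",
    "parse_exon_list",
    "FixtureError",
]

_ACCESSIONS = [f"ON0810{n}" for n in range(37, 46)]
_EXON_RE = re.compile(r"^Exon (\d+)( \*)?$")


class FixtureError(ValueError):
    """A packaged fixture fails its integrity checks."""


def parse_exon_list(text: str) -> list[tuple[int, bool]]:
    """Parse an exon-list string like ``"Exon 3 *, Exon 4"``.

    Returns ``(exon_index, truncated)`` pairs in the printed order; the
    asterisk marks a truncated junction-forming exon.
    """
    out = []
    for token in text.split(", "):
        m = _EXON_RE.match(token.strip())
        if not m:
            raise FixtureError(f"malformed exon token {token!r} in {text!r}")
        out.append((int(m.group(1)), m.group(2) is not None))
    return out


def _read(name: str) -> pd.DataFrame:
    with resources.files("backsplice.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table1() -> pd.DataFrame:
    """The nine-circRNA catalog fixture, validated.

    Columns: circ_id, accession, cell_lines, exon_count, exons, length_nt.
    """
    df = _read("table1.tsv")
    if len(df) != 9:
        raise FixtureError(f"expected 9 circRNAs, found {len(df)}")
    if list(df["accession"]) != _ACCESSIONS:
        raise FixtureError("accession numbers must run ON081037..ON081045")
    for _, row in df.iterrows():
        exons = parse_exon_list(row["exons"])
        if len(exons) != row["exon_count"]:
            raise FixtureError(
                f"{row['circ_id']}: exon_count {row['exon_count']} != "
                f"{len(exons)} listed exons"
            )
    return df


def load_table2() -> pd.DataFrame:
    """The top-two predicted sponged miRNAs per circRNA, validated.

    Columns: circ_id, mirna_id, prediction_score, binding_motif (RNA).
    """
    df = _read("table2.tsv")
    counts = df.groupby("circ_id").size()
    if not (counts == 2).all():
        raise FixtureError("each circRNA must list exactly 2 miRNAs")
    if (df["prediction_score"] > 100).any() or (df["prediction_score"] < 0).any():
        raise FixtureError("prediction scores must be on a 0-100 scale")
    if not df["binding_motif"].str.fullmatch("[ACGU]+").all():
        raise FixtureError("binding motifs must be RNA strings")
    return df
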
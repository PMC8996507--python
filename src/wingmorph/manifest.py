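"""Published study manifest: species, per-wing sample sizes and habitat
assignments for the 27-species *Trithemis* dataset this package's analyses
were designed around.  Landmark configurations were digitized for every
specimen; specimens whose photographs showed the pinned label were excluded
from the image datasets, so the image columns sum lower (217 forewings, 227
hindwings) than the landmark columns (276 each)."""

from __future__ import annotations

from io import StringIO

import pandas as pd

_MANIFEST_CSV = """\
species,landmarks_forewing,images_forewing,landmarks_hindwing,images_hindwing,landscape,water_body
Trithemis aenea,4,4,4,4,forested,running
Trithemis aequalis,3,0,3,1,open,running
Trithemis annulata,20,12,20,13,open,standing
Trithemis arteriosa,10,10,10,10,open,standing
Trithemis aurora,10,10,10,10,open,standing
Trithemis bredoi,10,10,10,10,forested,running
Trithemis dichroa,16,12,16,8,forested,running
Trithemis donaldsoni,10,9,10,9,open,running
Trithemis dorsalis,10,1,10,6,open,running
Trithemis ellenbekii,11,4,11,6,open,running
Trithemis festiva,10,2,10,5,open,running
Trithemis furva,18,12,18,15,open,running
Trithemis grouti,10,9,10,10,forested,running
Trithemis hecate,8,7,8,8,open,standing
Trithemis imitata,10,7,10,3,open,standing
Trithemis kalula,10,10,10,10,open,standing
Trithemis kirbyi,19,15,19,17,open,standing
Trithemis monardi,9,9,9,9,open,standing
Trithemis nigra,10,10,10,10,forested,running
Trithemis nuptualis,10,6,10,5,forested,running
Trithemis persephone,5,5,5,5,forested,standing
Trithemis pluvalis,8,8,8,8,open,running
Trithemis purinata,10,10,10,10,forested,running
Trithemis selika,8,8,8,8,open,standing
Trithemis stictica,10,10,10,10,open,running
Trithemis tropicana,10,10,10,10,forested,running
Trithemis weneri,7,7,7,7,open,running
"""


def study_manifest() -> pd.DataFrame:
    """The published sample manifest as a DataFrame (one row per species)."""
    return pd.read_csv(StringIO(_MANIFEST_CSV))


def manifest_totals() -> dict:
    """Column sums of the manifest's sample-size columns."""
    df = study_manifest()
    cols = ["landmarks_forewing", "images_forewing",
            "landmarks_hindwing", "images_hindwing"]
    return {c: int(df[c].sum()) for c in cols}
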
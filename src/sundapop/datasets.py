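"""Built-in study design: the nine southeast-Asian sampling sites.

Coordinates, taxon labels and per-site sample sizes for the nine sites at
which *Bactrocera dorsalis s.l.* males were trapped (one site in Taiwan,
three in Thailand, two in peninsular Malaysia, one in Sumatra, two in the
Philippines).  ``n_genetics`` is the number of COI sequences per site
(total 156) and ``n_shape`` the number of wings landmarked (total 169).

``SUNDALAND_ARC`` orders the sites along the land margin of the South China
Sea: Taiwan across to mainland Thailand, down the Thai/Malay peninsula,
through Sumatra and up into the Philippines.  It is the default ordering for
the "path" geographic distance mode.
"""

from __future__ import annotations

import pandas as pd

from .geo import SiteTable

_SITES = [
    # site, taxon, lat, lon, n_genetics, n_shape
    ("Taipei", "B. dorsalis s.s.", "25°00'53\"N", "121°32'18\"E", 19, 20),
    ("San Pa Tong", "B. dorsalis s.s.", "18°37'37\"N", "98°53'42\"E", 19, 20),
    ("Bangkok", "B. dorsalis s.s.", "13°50'32\"N", "100°34'23\"E", 19, 20),
    ("Nakhon Si Thammarat", "B. dorsalis s.s.", "8°25'12\"N", "99°53'48\"E", 12, 20),
    ("Penang", "B. papayae", "5°28'33\"N", "100°17'51\"E", 20, 20),
    ("Serdang", "B. papayae", "3°00'20\"N", "101°42'00\"E", 22, 20),
    ("Lampung", "B. papayae", "5°40'43\"S", "105°36'38\"E", 15, 14),
    ("Quezon City", "B. philippinensis", "14°38'00\"N", "121°01'00\"E", 17, 20),
    ("Imus", "B. philippinensis", "14°07'18\"N", "120°58'00\"E", 13, 15),
]

SUNDALAND_ARC = [
    "Taipei",
    "San Pa Tong",
    "Bangkok",
    "Nakhon Si Thammarat",
    "Penang",
    "Serdang",
    "Lampung",
    "Imus",
    "Quezon City",
]

#: Five site groups from the post-hoc clustering of the genetic MDS plot,
#: used for the hierarchical AMOVA.
MDS_GROUPS = {
    "Taiwan/Thailand": ["Taipei", "San Pa Tong", "Bangkok", "Nakhon Si Thammarat"],
    "Peninsular Malaysia": ["Penang", "Serdang"],
    "Sumatra": ["Lampung"],
    "Philippines A": ["Quezon City"],
    "Philippines B": ["Imus"],
}


def study_sites() -> SiteTable:
    """The nine-site sampling design as a :class:`~sundapop.geo.SiteTable`."""
    df = pd.DataFrame(
        _SITES, columns=["site", "taxon", "lat", "lon", "n_genetics", "n_shape"]
    )
    return SiteTable(df)
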
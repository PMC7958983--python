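"""Canonical catalog of the 39 intimate-partner-violence questionnaire items.

The survey instrument groups items into three original subscales: physical
violence (PV, 12 items), sexual violence (SV, 22 items) and psychological
aggression (PA, 5 items).  Occurrence-pattern analysis reassigns three items,
yielding the working four-type catalog: PV=10, PA=5, SV=23 and a single
micro-aggression (MA) item:

* PA3 ("called you names ...") becomes the micro-aggression item MA1,
* PV1 ("made threats to physically harm you") becomes PA6,
* PV8 ("forced you to engage in sexual activity") becomes SV22.

Four SV item IDs (SV8, SV13, SV14, SV17) are not published with the
instrument text; synthetic placeholder entries keep the subscale at its
stated 22-item (pre-reassignment) size.  Their labels are marked
``[synthetic placeholder]``.
"""

from __future__ import annotations

#: (original_id, reassigned_id, original_type, label)
ITEM_DEFS: list[tuple[str, str, str, str]] = [
    ("PA1", "PA1", "PA", "acted very angry towards you in a way that seemed dangerous"),
    ("PA2", "PA2", "PA", "told you that you were a loser, a failure, or not good enough"),
    ("PA3", "MA1", "PA", "called you names like ugly, fat, crazy, or stupid"),
    ("PA4", "PA4", "PA", "insulted, humiliated, or made fun of you in front of others"),
    ("PA5", "PA5", "PA", "told you that no one else would want you"),
    ("PV1", "PA6", "PV", "made threats to physically harm you"),
    ("PV2", "PV2", "PV", "slapped you"),
    ("PV3", "PV3", "PV", "pushed or shoved you"),
    ("PV4", "PV4", "PV", "hit you with a fist or something hard"),
    ("PV5", "PV5", "PV", "kicked you"),
    ("PV6", "PV6", "PV", "hurt you by pulling your hair"),
    ("PV7", "PV7", "PV", "slammed you against something"),
    ("PV8", "SV22", "PV", "forced you to engage in sexual activity"),
    ("PV9", "PV9", "PV", "tried to hurt you by choking or suffocating"),
    ("PV10", "PV10", "PV", "beaten you"),
    ("PV11", "PV11", "PV", "burned you on purpose"),
    ("PV12", "PV12", "PV", "used a knife or gun on you"),
    ("SV1", "SV1", "SV", "exposed their sexual body parts to you, flashed you, or masturbated in front of you"),
    ("SV2", "SV2", "SV", "made you show your sexual body parts to them"),
    ("SV3", "SV3", "SV", "made you look at or participate in sexual photos or movies"),
    ("SV4", "SV4", "SV", "harassed you while you were in a public place in a way that made you feel unsafe"),
    ("SV5", "SV5", "SV", "kissed you in a sexual way"),
    ("SV6", "SV6", "SV", "fondled or grabbed your sexual body parts"),
    ("SV7", "SV7", "SV", "had vaginal sex with you while you were unable to consent"),
    ("SV8", "SV8", "SV", "unpublished sexual violence item [synthetic placeholder]"),
    ("SV9", "SV9", "SV", "made you receive anal sex while you were unable to consent"),
    ("SV10", "SV10", "SV", "made you perform oral sex while you were unable to consent"),
    ("SV11", "SV11", "SV", "made you receive oral sex while you were unable to consent"),
    ("SV12", "SV12", "SV", "used physical force or threats to physically harm you to make you have vaginal sex"),
    ("SV13", "SV13", "SV", "unpublished sexual violence item [synthetic placeholder]"),
    ("SV14", "SV14", "SV", "unpublished sexual violence item [synthetic placeholder]"),
    ("SV15", "SV15", "SV", "used physical force or threats to make you perform oral sex"),
    ("SV16", "SV16", "SV", "used physical force or threats to make you receive oral sex"),
    ("SV17", "SV17", "SV", "unpublished sexual violence item [synthetic placeholder]"),
    ("SV18a", "SV18a", "SV", "tried to make you have vaginal sex with them, but sex did not happen"),
    ("SV18b", "SV18b", "SV", "tried to have vaginal, oral, or anal sex with you, but sex did not happen"),
    ("SV19", "SV19", "SV", "pressured you by telling lies, making untrue promises, or threatening your relationship or reputation"),
    ("SV20", "SV20", "SV", "pressured you by wearing you down, repeatedly asking for sex, or showing unhappiness"),
    ("SV21", "SV21", "SV", "pressured you by using their influence or authority over you"),
]

#: Reassigned item IDs in canonical column order: MA first, then PA, PV, SV.
CANONICAL_ORDER: list[str] = (
    ["MA1"]
    + ["PA1", "PA2", "PA4", "PA5", "PA6"]
    + [f"PV{k}" for k in (2, 3, 4, 5, 6, 7, 9, 10, 11, 12)]
    + [f"SV{k}" for k in range(1, 18)]
    + ["SV18a", "SV18b", "SV19", "SV20", "SV21", "SV22"]
)

#: The three reassignments, keyed by original item ID.
REASSIGNMENTS: dict[str, tuple[str, str]] = {
    "PA3": ("MA1", "MA"),
    "PV1": ("PA6", "PA"),
    "PV8": ("SV22", "SV"),
}


def assigned_type(item_id: str) -> str:
    """Violence type implied by a reassigned item ID prefix."""
    for t in ("MA", "PA", "PV", "SV"):
        if item_id.startswith(t):
            return t
    raise ValueError(f"item ID {item_id!r} has no recognized type prefix")
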
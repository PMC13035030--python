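"""Hand-annotated 30-document multilingual filter fixture.

Each entry: (doc_id, text, language, retained) where ``retained`` is the
hand-derived verdict of whole-token, case-insensitive descriptor
matching against the default 15-term pandemic list.  Compounds like
"Pandemiebekämpfung" and hyphenated tokens like "Corona-Kurs" must NOT
match ("covid-19" is itself on the list and is one token).
"""

from __future__ import annotations

import datetime as dt

from seednet import Corpus, Document

ANNOTATED_DOCS: list[tuple[str, str, str, bool]] = [
    ("m01", "Die Pandemie dauert an.", "de", True),
    ("m02", "Die Seuche breitet sich rasch aus.", "de", True),
    ("m03", "L'épidémie continue en Suisse romande.", "fr", True),
    ("m04", "La pandemia ha cambiato tutto.", "it", True),
    ("m05", "Covid-19 bleibt ein grosses Thema.", "de", True),
    ("m06", "Das Virus mutiert weiter.", "de", True),
    ("m07", "Der Corona-Kurs der Regierung wird diskutiert.", "de", False),
    ("m08", "Das Coronavirus verbreitet sich schnell.", "de", True),
    ("m09", "The pandemic changed everything last year.", "en", True),
    ("m10", "An epidemic outbreak was reported yesterday.", "en", True),
    ("m11", "La pandémie a profondément marqué le pays.", "fr", True),
    ("m12", "Die Epidemie ist offiziell vorbei.", "de", True),
    ("m13", "Un'epidemia di paura si diffonde.", "it", True),
    ("m14", "covid zahlen steigen wieder an.", "de", True),
    ("m15", "CORONA ist in allen Schlagzeilen.", "de", True),
    ("m16", "Guten Morgen zusammen!", "de", False),
    ("m17", "Die Grippe ist dieses Jahr harmlos.", "de", False),
    ("m18", "Er trinkt ein Corona an der Bar.", "de", True),
    ("m19", "Bonjour tout le monde, belle journée.", "fr", False),
    ("m20", "Il tempo è bello oggi a Lugano.", "it", False),
    ("m21", "Nothing to see here, move along.", "en", False),
    ("m22", "Die Viruserkrankung nimmt zu.", "de", False),
    ("m23", "Pandemiebekämpfung ist eine Daueraufgabe.", "de", False),
    ("m24", "Covid19 ohne Bindestrich geschrieben.", "de", False),
    ("m25", "Die Seuchenprävention wurde verstärkt.", "de", False),
    ("m26", "Das Virusprogramm läuft auf dem Computer.", "de", False),
    ("m27", "Der Ausbruch der Panik blieb aus.", "de", False),
    ("m28", "L'épidémiologie est une science fascinante.", "fr", False),
    ("m29", "Fehlinformation überall, aber kein Deskriptor.", "de", False),
    ("m30", "Hände waschen hilft immer.", "de", False),
]

EXPECTED_RETAINED_IDS = [d[0] for d in ANNOTATED_DOCS if d[3]]


def build_corpus() -> Corpus:
    docs = tuple(
        Document(
            doc_id=doc_id,
            text=text,
            date=dt.date(2021, 1, 1),
            source="fixture",
            language=lang,
            channel="social",
        )
        for doc_id, text, lang, _ in ANNOTATED_DOCS
    )
    return Corpus(docs, provenance="multilingual-fixture")
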
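"""Builtin function-word lists for the four supported languages.

Deliberately small: articles, pronouns, prepositions, auxiliaries and
high-frequency adverbs/conjunctions.  Content words are never listed —
the co-occurrence figures show content lemmas only, so function words
are removed by default (``stopword_policy="builtin"``).
"""

from __future__ import annotations

GERMAN = frozenset("""
aber alle allem allen aller alles als also am an andere anderen auch auf aus
bei beim bin bis bist da damit dann das dass de dem den denn der des dessen
dich die dies diese diesem diesen dieser dieses dir doch du durch ein eine
einem einen einer eines er es etwas für gegen hab habe haben hat hatte hatten
hier hin hinter ich ihm ihn ihnen ihr ihre im in ins ist ja je jede jedem
jeden jeder jedes kann kein keine keinem keinen können mal man mehr mein
meine mich mir mit muss nach nicht nichts noch nun nur ob oder ohne schon
sehr sei sein seine sich sie sind so soll sollte über um und uns unser unter
vom von vor war waren was weil wenn werden wie wieder wir wird wurde wurden
zu zum zur zwischen
""".split())

FRENCH = frozenset("""
au aux avec ce ces cette dans de des du elle elles en et eux il ils je la le
les leur lui ma mais me même mes moi mon ne nos notre nous on ou où par pas
plus pour qu que qui sa se ses son sur ta te tes toi ton tu un une vos votre
vous y a été être sont est avait ont
""".split())

ITALIAN = frozenset("""
a ad agli ai al alla alle allo anche che chi ci coi col come con contro cui
da dagli dai dal dalla dalle dallo degli dei del della delle dello di dove e
ed gli ha hanno i il in la le lei lo loro lui ma mi ne nei nel nella nelle
nello noi non o per però più quella quelle quelli quello questa queste
questi questo se si sono su sua sue sui sul sulla suo tra un una uno voi è
""".split())

ENGLISH = frozenset("""
a about after all also an and any are as at be because been before being but
by can could did do does for from had has have he her him his how i if in
into is it its may more most my no not of on one only or other our out over
she so some such than that the their them then there these they this to
under up was we were what when which who will with would you your
""".split())

BY_LANGUAGE = {"de": GERMAN, "fr": FRENCH, "it": ITALIAN, "en": ENGLISH,
               "und": frozenset()}
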
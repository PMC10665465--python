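"""Choose a composite terminal for one genus.

Five sequence records from three species across three markers: the
greedy selection covers every marker with as few species as possible,
then keeps the longest sequence per marker among the chosen species.
"""

from angiodiv import dedupe_longest, greedy_select
from angiodiv.supermatrix import SequenceRecord


def rec(species, marker, length, date="2015-01-01"):
    return SequenceRecord(species=species, genus="Sedum", marker=marker,
                          length=length, date=date,
                          accession=f"{species}|{marker}")


records = dedupe_longest([
    rec("S_acre", "matK", 800),
    rec("S_acre", "ITS", 600),
    rec("S_album", "ITS", 500),
    rec("S_album", "rbcL", 1300),
    rec("S_rubens", "rbcL", 1400),
    rec("S_acre", "ITS", 550),       # shorter duplicate, dropped by dedupe
])

sel = greedy_select(records)
print(f"species used: {sorted(sel.species_used)} (composite: {sel.composite})")
for marker, r in sorted(sel.per_marker.items()):
    print(f"  {marker:5s} <- {r.species} ({r.length} bp)")
print("S_rubens's longer rbcL is ignored: species are chosen for marker "
      "coverage, and sequences then come only from the chosen species.")
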
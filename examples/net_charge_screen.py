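"""Net-charge statistic over a set of protein constructs.

Counts +1 per lysine/arginine and -1 per aspartate/glutamate (histidine
uncharged) — the simple electrostatic summary that separates strongly
negative GTPase G-domains from near-neutral ones.
"""

from rhoselect import SequenceRecord, charge_table

records = [
    SequenceRecord("acidic_surface", "MDEDEAKKLDEEFGHDEDA"),
    SequenceRecord("balanced", "MKRDEAKKLDEEFRHKRDA"),
    SequenceRecord("basic_patch", "MKRKKAKKLGQRFRHKRKA"),
]
table = charge_table(records)
print(table.to_string(index=False))
print("\nnet_charge = (K + R) - (D + E); a span of several units across "
      "paralogs predicts very different electrostatic potentials.")
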
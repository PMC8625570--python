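"""Map an interface and classify hotspot positions against it.

Builds a toy two-chain complex with three engineered atomic contacts,
detects interfacial residues (heavy atoms within 4.5 A of the partner
chain) and classifies a few residue positions as interface / proximal /
distal.
"""

from rhoselect import (generate_toy_complex, hotspot_proximity,
                       interface_residues)

atoms = generate_toy_complex(n_contact_pairs=3, separation=4.0, seed=1)
report = interface_residues(atoms, group_a={"A"}, group_b={"B"}, cutoff=4.5)

print("chain A interface residues:",
      sorted(num for _, num, _ in report.interface_a))
classes = hotspot_proximity(report, [1, 2, 4, 99], near=8.0)
print("hotspot classification:", classes)
print("Positions inside the contact set are 'interface'; within 8 A "
      "'proximal'; residues absent from the model are 'unresolved'.")
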
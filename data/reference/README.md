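# Reference sequence inputs (user-supplied)

The package never downloads data. The checks and `reproduce` commands that
concern *real* protein sequences read plain FASTA files from this
directory, which you must create yourself from UniProt (www.uniprot.org).
All other analyses run entirely from packaged synthetic fixtures and need
nothing here.

Expected files, using the package FASTA header dialect
(`>id accession=ACC range=start-end label=...`):

## `rho_gtpases.fasta`

G-domain sequences of the RHO-family GTPases screened against IQGAP1/2,
one record per protein, ids lowercase. Fetch each accession and keep the
G-domain construct range:

| id    | accession | range  | label     |
|-------|-----------|--------|-----------|
| rac1  | P63000    | 1-179  | binder    |
| rac2  | P15153    | 1-192  | binder    |
| rac3  | P60763    | 1-192  | binder    |
| rhog  | P84095    | 1-178  | binder    |
| cdc42 | P60953    | 1-178  | binder    |
| rhoa  | P61586    | 1-181  | nonbinder |
| rhob  | P62745    | 1-181  | nonbinder |
| rhoc  | P08134    | 1-181  | nonbinder |
| tc10  | P17081    | 2-193  | nonbinder |
| rnd1  | Q92730    | 1-232  | nonbinder |
| rnd2  | P52198    | 26-184 | nonbinder |
| rnd3  | P61587    | 1-244  | nonbinder |
| rif   | Q9HBH0    | 1-195  | nonbinder |
| rhod  | P97348    | 2-193  | nonbinder |

## `iqgap_fragments.fasta`

The C-terminal IQGAP fragments:

| id     | accession | range    |
|--------|-----------|----------|
| iqgap1 | P46940    | 863-1657 |
| iqgap2 | Q13576    | 780-1575 |

## `rho_gdomain_alignment.fasta`

Aligned FASTA ('-' gaps) of the 14 G-domains above with the same ids and
labels, e.g. produced with `mafft` from `rho_gtpases.fasta`; the `cdc42`
row is the numbering reference.
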
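# Provenance notes on the bundled karyotype tables

The files under `profiles/` transcribe the published per-pair karyotype
tables (relative length %, arm ratio, centromere type) for nine Brazilian
*Smilax* accessions; `table1.tsv` transcribes the companion summary table
(chromosome length range, largest/smallest ratio, haploid-set length) plus
the published karyotype formula and Stebbins class for each accession.

Two corrections / caveats carried over from the source tables:

1. *S. polyantha* (Mogi Guaçu), pair 11: the relative length is printed as
   "4.91/491" — an evident typo for "4.91/4.91"; the fixture stores
   `4.91/4.91`.
2. *S. polyantha* (Mogi Guaçu), summary row: the printed largest/smallest
   ratio (2.80) is inconsistent with the quotient of the printed extreme
   lengths (5.36/1.94 = 2.76).  The row is flagged `consistent_ratio = 0`
   and excluded from quotient-reproduction checks.

Further known internal inconsistencies of the source (not "fixed" here):
the relative-length columns of several accessions do not sum to ~100
(e.g. 103.3–113.5 for the two *S. fluminensis* accessions, *S. polyantha*
Botucatu and *S. brasiliensis*), and relative lengths are not everywhere
monotone in rank (*S. fluminensis* Uruana ranks 11/12).  The summary-table
length ranges and the per-pair relative lengths are mutually inconsistent
for several accessions — presumably one reflects a single spread and the
other a mean of at least five — so no cross-table equality is asserted
anywhere in the package.
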
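# Optional external validation against real honeybee assemblies

The test suite and acceptance script score every analysis against the
synthetic generator's planted truth, entirely offline.  The published
assembly-scale figures for the honeybee genome — for example the
~12.8 Mbp of simple repeats/low-complexity sequence, the ~191.6 Mbp of
same-chromosome whole-genome alignments between the hybrid and the
previous assembly, the AluI/AvaI fold enrichments between assembly
versions, and the 16,463 bp mitochondrion — require both real assemblies
and external annotation tools, so they are **not** recomputed here.
They can be reproduced with this package as follows.

Inputs to obtain (not redistributed with this package):

1. The chromosome-scale hybrid honeybee (*Apis mellifera*) assembly and
   the previous short-read assembly, each as FASTA, with their
   scaffold-to-chromosome placement tables.
2. The consensus FASTA of the centromeric 547 bp AvaI repeat and the
   proximal-telomeric 176 bp AluI repeat (GenBank consensus entries);
   pass them to `annotate_canonical` in place of the synthetic stand-in
   consensus sequences shipped in `chromofeat.canonical`.
3. The microsatellite linkage-map marker table (marker id, linkage
   group, position in cM, two primer sequences) as TSV.

Recipe:

1. `chromofeat stats` and `chromofeat gc --window 10000` on both
   assemblies reproduce the overall size/N50/L50 and GC summaries.
2. Run RepeatMasker against a metazoan library extended with the
   AvaI/AluI consensus sequences; feed the pre-ProcessRepeats
   `ori.out` into `read_repeatmasker_out(path, dialect="ori")`,
   then `resolve_overlaps` → `find_tandem_arrays` →
   `summarize_repeats`/`compare_summaries` for the per-family bp and
   count fold differences, and `array_membership_quantile` for the
   "half of all copies in arrays of ≥ c copies" statistics.
3. `chromofeat scan-telomeres` on both assemblies reproduces the distal
   telomere calls, background densities and fold enrichments;
   `chromofeat telomere-profile` on a MAFFT L-INS-i alignment of the
   chromosome ends reproduces the divergence/variant-density profile.
4. `chromofeat find-centromeres` reproduces the low-GC centromere
   regions; `chromofeat recomb-rate --regions centromeres.bed` the
   genome-wide and centromeric cM/Mbp estimates.
5. Align the older assembly against the newer one with Satsuma (or any
   tool emitting block coordinates), convert to the blocks TSV layout,
   and run `chromofeat compare-assemblies` for the per-category bp
   totals and `region_feature_stats` for the per-category feature means.

None of these published values is asserted by the test suite; the
package computes them only when given the external inputs above.
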
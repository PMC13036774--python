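# depsitools

Analysis toolkit for the discovery and comparative genomics of **cyclic
lipodepsipeptides** — bacterial natural products built from a peptide
macrolactone and a β-hydroxy fatty-acyl chain, assembled by modular
nonribosomal peptide synthetases (NRPS). It is written for natural-product
chemists and microbial genome miners who want to go from raw MS/MS spectra
and NRPS gene-cluster annotations to annotated structures, congener
families, and evolutionary hypotheses, reproducibly and from the command
line.

The package covers four stages of a peptidogenomic workflow:

1. **Exact-mass chemistry** (`depsitools.chem`) — Hill-notation formula
   arithmetic, monoisotopic masses, protonated-adduct *m/z*
   ((M + n·1.00727646)/z), signed ppm deviations
   ((obs − calc)/calc × 10⁶), and ring-plus-double-bond equivalents
   (C − H/2 + N/2 + 1).
2. **MS/MS ladder annotation** (`depsitools.fragments`) — ring-opened
   b/y ion series for acylated depsipeptides with the diagnostic neutral
   losses b° (−H₂O), b\* (−HNCO, citrulline's ureido group), and
   b# (loss of the fatty-acyl increment); peptidogenomic candidate
   ranking; and congener mass-shift localization (+O hydroxylations,
   ±CH₂ acyl homologs).
3. **Classic molecular networking** (`depsitools.network`) — precursor
   ±17 Da exclusion, top-6-per-±50 Da window filtering, modified cosine
   with 0.02 Da fragment tolerance and exact maximum-weight peak pairing,
   edges at cosine > 0.7 with ≥ 6 matched peaks, mutual top-10 rank
   filtering, and molecular-family size capping at 100.
4. **NRPS gene-cluster evolution** (`depsitools.bgc`) — starter-condensation
   (C_Starter) domain harvesting from clusters with > 5 adenylation
   domains, global alignment and percent identity, sliding-window
   nucleotide diversity π (300 nt windows, 150 nt steps), exact-word dot
   plots, module-duplication detection at ≥ 90 % nucleotide identity,
   deletion-breakpoint localization to inter-domain linkers, and
   neighbor-joining trees with seeded bootstrap.

A first-class simulator (`depsitools.simulate`) generates ground-truth
MS/MS spectra, congener series, and NRPS cluster families with planted
duplications, recombinations and deletions, so every detector in the
package is tested against known answers.

## Worked example

The flagship compound is a 12-residue macrolactone
(Orn1–His2–Val3–OHPro4–Gly5–Cit6–OHTrp7–Gly8–Trp9–Gly10–Val11–Asp12,
N-acylated with a 3-hydroxy-14-methylpalmitoyl chain, ester-closed on
Asp12) with molecular formula C₈₁H₁₁₉N₁₉O₁₉:

```
$ depsitools mass --formula C81H119N19O19 --adduct M+H --observed 1662.8956
formula	C81H119N19O19
monoisotopic_mass	1661.8930
calcd_mz	1662.9002
rdbe	32
ppm_deviation	-2.79
```

The neutral monoisotopic mass is 1661.8930 Da, the calculated [M+H]⁺ is
1662.9002, the 32 ring-plus-double-bond equivalents account for the 12
amide bonds, the side-chain unsaturations and the macrocycle, and the
observed ion deviates by −2.8 ppm from the calculated adduct.

Simulate the six-member congener family and annotate it with the
theoretical ladder of the parent peptide:

```
$ depsitools simulate --out-dir demo --seed 1
wrote 6 spectra to demo/congeners.mgf
$ depsitools annotate --mgf demo/congeners.mgf \
    --peptide "3-OH-14-Me-palmitoyl|Orn-His-Val-OHPro-Gly-Cit-OHTrp-Gly-Trp-Gly-Val-Asp"
congener_A	matched=110	ladder_coverage=1.000
congener_B	matched=60	ladder_coverage=1.000
congener_C	matched=52	ladder_coverage=1.000
congener_D	matched=48	ladder_coverage=1.000
congener_E	matched=48	ladder_coverage=1.000
congener_F	matched=22	ladder_coverage=1.000
```

Congener A is the parent: every one of its 110 theoretical ions is
present. The other congeners share the backbone, so every inter-residue
bond is still supported (coverage 1.0) through the unshifted half of the
b/y ladder, while the matched-ion count drops with increasing structural
difference. `depsitools congener` then assigns each precursor shift
(e.g. +15.9949 Da → hydroxylation at residue 9; −14.0157 Da → one CH₂
shorter acyl chain), and `depsitools network` groups the six spectra into
a single molecular family while leaving unrelated spectra apart.

For the genomic side, `depsitools harvest`, `pi`, `dotplot`, `dup` and
`tree` operate on domain-annotation TSVs and FASTA/aligned-FASTA files;
see `depsitools --help`.

## Layout

```
src/depsitools/
  chem.py       formulas, masses, adducts, ppm, RDBE, residue/acyl tables
  fragments.py  ion ladders, annotation, ranking, congener shifts
  network.py    peak filtering, modified cosine, network assembly
  bgc.py        alignment, identity, pi, dot plots, NJ trees, detectors
  simulate.py   spectrum / congener / BGC-family simulators
  io.py         MGF, mzML, domain TSV, FASTA, Newick, GraphML writers
  cli.py        the `depsitools` command
  data/         monoisotopic masses, residues, acyl chains (TSV)
docs/methods.md   models, conventions, parameter choices, limitations
```
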
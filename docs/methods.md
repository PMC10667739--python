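# Methods

`iplome` implements an informatics stack for environmental intact polar
lipid (IPL) analysis: in-silico combinatorial database generation,
MS1/MS2 annotation with isomer-resolution rules, semi-quantification
against response factors, and lipidome geochemistry statistics. This
note records the models, conventions and numerical choices, and what
the synthetic benchmarks do and do not demonstrate.

## Formula engine

Elemental formulas are integer element-count maps with a net charge.
Monoisotopic masses use CODATA/IUPAC isotope masses hard-coded to >= 9
decimals; ion m/z includes the electron mass (one electron removed per
positive charge, added per negative), which matters at Orbitrap-grade
(sub-ppm) accuracy. Deuterium (`D`) is a distinct symbol so deuterated
internal standards (d9-DGTS) get correct masses.

The nominal carbon oxidation state is

    Zc = (Z + 2o + 3n - 5p - 4s - h) / c

with `Z` the net charge and lower-case letters the atom counts (D
counts as h). Anchors: CH4 = -4, CO2 = +4. The sulfur coefficient -4 is
a convention inherited from the lipid-Zc literature; conventional
redox bookkeeping would use -2/+2 for thiols/sulfates, but no
sulfur-bearing lipid appears in the starter tables, so the choice has
no numerical effect here.

Four electrospray adducts are modeled — [M+H]+, [M+NH4]+ (positive),
[M-H]-, [M+HCOO]- (negative) — all singly charged.

## Theoretical database

A *component* is a headgroup + backbone pair. The starter data factors
each component's base formula into a headgroup net formula (the free
molecule minus H2O for the condensation bond) and a backbone skeleton
(the base formula at zero chain carbons, with linkage chemistry baked
in: each ester contributes +O -H2 relative to the free glycerol, each
ether nothing, the amide of a fatty-amide backbone a single carbonyl
O). Sanity anchors: PC-DAG 34:0 assembles to C42H84NO8P (761.5935 Da),
monoacylglycerol/di-/tri-acyl and cardiolipin skeletons reproduce
monopalmitin, tripalmitin and tetraoleoyl-cardiolipin formulas.

Chain states iterate totals (C, double bonds, hydroxylations). Per
chain: 2-30 carbons, 0-6 double bonds, with the "3n + 2" spacing rule
interpreted as: d methylene-interrupted double bonds need a chain of at
least 3(d-1)+2 carbons. The predicate is isolated in
`ChainConstraints.chain_allows` so the interpretation can be swapped;
the test-suite brute-force oracle re-implements it independently.
Hydroxylations are budgeted per species (0-3), not per chain, and
positions are not tracked (formula-level only). Species are identified
by totals; distinct per-chain decompositions collapse to one entry, so
a 2-chain enumeration is the self-convolution of the 1-chain set.

Full-structure ("unique") components — archaeol, isoprenoidal and
branched GDGTs, GDDs, ladderanes — expand a core formula over
modification grids: unsaturation -H2, ring/DBE -H2, methylation +CH2,
hydroxylation +O, isoprene-unit extension/abridgement +/-C5H10.
Archaeol's unsaturation grid runs 1-8 with the unmodified core included
as an explicit base entry (plain 1G-AR must exist). Ladderane cores are
entered as glycerol diesters of two identical ladderane fatty acids
(ring count 3 or 5, chain 18-22 C); only ring and carbon counts are
constrained by observation, so these rows are documented conventions,
replaceable by the user.

Composite names follow `HG-BB C:U [+ kO]` (e.g. `PG-DAG 34:0 + 1O`);
unique cores use their label plus signed modification tokens
(`1G-AR + 2u + 1Ip`). `format_name`/`parse_name` are exact inverses
over everything the generator emits.

The database is a (species x adduct) table sorted by m/z then name,
unique on (name, adduct), with every m/z recomputable from its formula
to 1e-6, an optional 400-2000 m/z scan-range filter (off by default:
whether published database sizes were counted before or after a scan
window is generally unstated), and a SHA-256 content hash for
reproducibility. The starter tables (25 components over 13 headgroups
and 8 iterative backbones, plus 7 unique cores) yield 123,748 ionized
entries under default constraints; the table is user-extensible and the
counts are validated against the brute-force oracle, not against any
published total.

## Annotation

MS1 matching is a ppm window (default 2.5 ppm, suited to 70k-resolution
full scans) on a sorted m/z index, polarity-aware, returning all
isomers. MS2 rules (default 10 ppm with a 1 mDa floor, for 17.5k MS2
resolution) are fragments (the rule formula is the ion's composition)
or neutral losses (a neutral moiety lost from the precursor), each
targeting a headgroup or backbone. All starter rule masses are computed
from formulas at load time. Positive mode characterizes headgroups
(e.g. phosphocholine 184.0733, hexose loss 162.0528); negative mode
probes the core: ester- and amide-linked chains appear as fatty-acid
carboxylate anions, and a candidate is "directly confirmed" when its
chain totals decompose into observed anions. Pure-ether species (DEG,
MEG) diagnostically lack negative-mode fragmentation and are never
required to show it. A backbone-level positive-mode rule (loss of H2O,
the sphingoid dehydration hallmark) marks ceramides, which separates
the Cer [M+H]+ / alkanediol [M+NH4]+ ion twins.

Isomer resolution is deterministic: (1) negative-mode chain evidence
fixes the structure; (2) otherwise a confirmed same-headgroup lipid
within 15 s retention time donates its backbone linkage (nearest |dRT|
wins, then lexicographic name); (3) otherwise the isomer requiring no
hydroxylation is chosen, with residual exact-isomer ties broken in
favor of pure-ether structures (absence of ester fragments argues for
the diether) and then by name. Every annotation carries provenance
(direct / neighbor-transfer / no-hydroxylation-default) and a
confidence tier; MS1-only annotations (no MS2, or MS2 that fired no
rule) are excluded from quantification.

## Quantification

Lipids must exceed 10x the mean solvent-blank area (strict inequality;
a zero blank mean always retains; pooled blank mean per lipid). Areas
are then multiplied by (pure / in-sample) response of the d9-DGTS
internal standard, so matrix suppression inflates areas back; the
reading of the correction direction is ambiguous in common wordings,
and an `invert` flag applies the reciprocal. Response factors are OLS
slopes (intercept fitted and discarded; through-origin behind a flag)
of area on injected mass over the 0.1/1/2.5/5/10 ng dilution series.
Classes without their own standard borrow by headgroup similarity:
aminolipids (OL, 3Me-OL, DGCC) -> DGTS; nitrogen-bearing glycolipids
(NAcG-G, NAcG-P, 1G-GA) -> DG-Cer; multi-glycosyl glycolipids (GAc-G,
2G) -> DG-DAG; classes with several standards use the mean slope.
Concentration = (corrected area / slope) / liters filtered, in ng/L.
Semi-quantitative by construction; extraction-recovery correction is
out of scope.

## Statistics

Mole fractions divide concentrations by neutral monoisotopic mass
before normalizing (mass fractions behind a flag). The
abundance-weighted property is Xi = sum(Xi_i x_i) / sum(n_i x_i) with
per-lipid property totals and component (chain) counts.

Zc partitions split each neutral formula into headgroup (the tabulated
net formula), backbone (a tabulated chunk), and chains (the exact
remainder, so conservation is structural). Glycerol-family backbones
partition as the full glycerol unit C3H8O3 (zc -2/3); the ceramide
chunk is calibrated to C4H10NO2 (sphingoid C1-C3 plus the amide carbon,
N and both oxygens, hydrogens by formal closure) so that its zc is
exactly -0.75 — the single available anchor; the delineation of shared
hydrogens between parts is otherwise under-determined and the table is
shipped as data, not code. Weighted Zc of a part is carbon-weighted:
sum(x_i e_i) / sum(x_i c_i) with e the Zc numerator — equivalent to the
Xi equation with e as the property and carbon count as the component
count — so carbon-free chunks (the fatty-amide backbone, a single
carbonyl O plus the N counted with the amine headgroup) contribute
their electron bookkeeping without breaking the mean; an error is
raised only when a sample's total part carbon is zero. A plain
mole-fraction-weighted mean of per-lipid zc values is available for
sensitivity checks.

Taxa-lipid association is Pearson correlation across shared samples
(>= 3) on untransformed relative abundances, with Bonferroni correction
(m = number of testable pairs; zero-variance vectors reported untested
and excluded from m). Compositional-data caveats apply and are not
"fixed" here. Ordination preprocessing: Hellinger transform
(sqrt of row proportions, unit sum-of-squares rows) and Gower
dissimilarity (mean range-normalized absolute difference over
informative columns, in [0, 1], zero diagonal); the constrained
ordination itself is left to dedicated ordination software.

## Synthetic data

The generator draws ground-truth lipids from a database (positive-mode,
non-hydroxylated entries spread over headgroups; lognormal true
concentrations with median ~5 ng/L, the dilute range of oligotrophic
waters; 3 samples of 20 L by default) and runs the forward model:
area = ng-on-column x class slope x per-sample matrix suppression x
lognormal(CV) noise, m/z perturbed by Gaussian ppm noise, retention
time = per-class slot (60 s apart) + 0.8 s/C - 2 s/double bond
+ 12 s/hydroxylation + uniform jitter (chain composition genuinely
shifts HILIC retention by minutes, and a flat per-class RT would make
every same-class pair a "15-s neighbor"). Positive MS2 carries the
class's diagnostic (plus the ceramide water loss); negative MS2, for a
configurable fraction of ester/amide species, carries fatty-acid
anions of one valid chain split. Blanks, the d9-DGTS responses and
exactly linear dilution series complete the dataset. A single seed
threads through all draws; runs are bit-reproducible.

Truth draws are restricted to backbone classes identifiable under the
modeled evidence (DAG, DEG, AEG, Cer, FA). Monoether and alkanediol
species are exact mass twins of diethers (MEG C:d = DEG C:d; AD 58:9 =
DEG 55:10; archaeol = DEG 40:0) that mass, headgroup diagnostics and
chain fragments cannot separate — real studies separate them
chromatographically or with authentic standards, which this simulator
does not model. Passing benchmarks therefore demonstrate correctness of
the pipeline logic under the modeled evidence, not isomer resolution
power beyond it.

Benchmark conditions: the invertibility check runs a zero-noise
scenario with complete MS2 evidence at 0.5 ppm MS1 tolerance (matched
to zero mass error) and must recover names and concentrations exactly;
the accuracy check runs 50 lipids at 2.5 ppm (1 sigma) m/z noise and
CV 0.05 area noise, annotated at 7.5 ppm (3 sigma) tolerance, and
requires >= 95% correct species assignment and <= 10% median relative
concentration error. Degradation of recovery is checked to be monotone
in noise over a small seed grid.

## Limitations

- Isomer resolution is formula-level; double-bond positions, sn
  positions and branching are out of scope, and nC does not distinguish
  branched from straight chains.
- The starter component, rule and partition tables cover the classes a
  serpentinite-hosted or oligotrophic-water lipidome features most
  prominently; they are inputs, not fixed truth, and real studies
  should extend them.
- The ceramide partition chunk is validated against a single anchor
  value; other delineations consistent with that anchor exist.
- Peak detection, alignment, isotope-envelope annotation and raw-file
  handling are upstream concerns; the package consumes aligned feature
  tables and centroided MS2 spectra.
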
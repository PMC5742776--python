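# Methods

## Digestion model

A protease is a set of positional rules over the residues surrounding a
peptide bond, in Schechter–Berger notation: P4–P1 on the N-terminal side of
the scissile bond, P1′–P2′ on the C-terminal side.  A rule is a map from
position labels to allowed residue sets; a bond is cut iff some rule matches
it and no exception rule does.  Digestion is *exhaustive*: every matching
bond is cut simultaneously, so there are no missed-cleavage combinatorics
and the released fragments always concatenate back to the substrate.  This
matches the behaviour of the online digestion tools the workflow emulates;
kinetic or partial digestion is out of scope.

Conventions that matter for edge cases:

* Bond `i` lies between residues `i` and `i+1` (0-based); fragments are
  0-based half-open slices.  "Cleavage" before the first or after the last
  residue releases nothing and is never emitted.
* A rule whose constrained position falls outside the sequence does not
  match there (the same convention as regex look-around).  Consequently
  rules constraining only P1/P1′ behave identically at fragment termini and
  in the parent protein, which is why exhaustive digestion is idempotent for
  such rule sets; rules reaching P2 and beyond can see different context at
  a fragment terminus, so idempotence is only asserted for the P1/P1′ case.
* The undetermined residue `X` (present in the Avenin-A fixture) matches no
  residue set, so no bond adjacent to an X is ever cut.

Rule tables are data, not code (`src/oatpep/data/rules/*.rules`), one file
per enzyme in a line-oriented format (`RULE P1={K,R} P1'=!{P}`, where
`!{...}` is the complement within the 20 standard residues).  Users can
align them with any revision of an external digestion service and re-check
with `oatpep validate-rules`.

### Gastrointestinal panel

Trypsin and the two chymotrypsin specificities encode the published
PeptideCutter conventions verbatim, including the positive Keil exceptions
(W‑K|P and M‑R|P for trypsin); the test suite cross-checks them against an
independent regex implementation of the same conventions.  The pepsin tables
(pH 1.3 and pH > 2) encode the simpler Keil-style preference — cleavage when
Phe/Leu (plus Trp/Tyr at pH > 2) occupies P1 or P1′, blocked by Pro at P1′
and by Pro/His at P1 — rather than PeptideCutter's full context table
(which additionally conditions on P3 and P2′).  The full context table
predicts no internal cleavage in FPIL and would therefore call a second
peptide digestion-resistant, contrary to the published screen; the
preference form reproduces all nine published resistance calls (only CPA
resistant).  A peptide is resistant iff no panel enzyme cuts any *internal*
bond; a C-terminal residue that would be a cut site in a longer context
releases nothing and is not counted.

### Release tables (papain, ficin) and calibration

No authoritative positional specificity table exists for the digestion
service that generated the published hydrolysates, and papain and ficin are
broad-specificity cysteine proteases.  The shipped tables are therefore
explicitly **calibrated starting points**: their rule sets were fit so that
the union of the papain and ficin exhaustive digests of the eight packaged
proteins contains every validation peptide — the 16 distinct previously
reported sequences plus the nine synthesised candidates — with papain alone
releasing CPA and WCY from the 11S globulin.  The calibration searched over
per-bond contexts (P2, P1, P1′) for two cut-sets satisfying each peptide's
boundary/internal bond constraints at some occurrence, then compressed the
result into product rules.  `validate_rules` is the permanent harness: for
any rule directory it reports per-peptide coverage and, for misses, which
boundary bonds would need to become cuttable and which internal bonds are
wrongly cut.  Coverage below 100% is reported, not hidden; the shipped
tables currently reach 25/25.

## Mass and solubility calculators

Masses use the ExPASy residue-mass tables (average and monoisotopic) plus
one water (18.0153 / 18.010565 Da).  The packaged proteins' printed
molecular masses follow the same convention and reproduce within 0.5 Da;
the printed peptide masses derive from a different tool's table and
reproduce within 0.022 Da, so the tests use 3 Da (proteins, after rounding)
and 0.05 Da (peptides) tolerances rather than reverse-engineering the source
tool.  Mass computation on X-containing sequences is refused — an
undetermined residue has no defensible mass — while the composition
fractions count X toward length only.

Solubility is the charged-residue heuristic of the PepCalc-style screen:
*good* iff charged_fraction = (#D+#E+#K+#R)/length ≥ 0.2, i.e. one charged
residue per five.  Histidine and the free termini are not counted; the nine
published calls (WWK and FEPL good, the other seven poor) contain no
histidine, so that choice is unconstrained by the reference data and is
documented rather than fitted.  The hydrophobic set used for composition
reporting is A,G,V,L,I,P,F,M,W — the same set as the renin N-terminal
criterion — since the source material never defines its "hydrophobic
residue content" set.

## Bioactivity criteria

The per-position residue sets are taken from the published tripeptide
characteristics; the literature states preferences per position but not how
positions combine, so the combination policy is explicit, configurable and
defaulted as: renin = N1 AND C; ACE-I = (N1 OR N2) AND any C alternative;
DPP-IV = N1 OR Xaa-Pro motif.  These defaults are the weakest conjunctions
consistent with all nine synthesised candidates passing at least one target.
Known limitations are inherited from the source criteria: WWK fails the
renin C-terminal (bulky) test although it was selected for renin testing on
N-terminal grounds — the engine follows the table; and the reported
affinity penalty for penultimate proline in ACE-I ligands (FEPL) is noted
but not encoded, as no quantitative rule is given.

Matching against the known-peptide table is exact full-sequence equality
(the entries are themselves exhaustive digest products); the
`occurrence_frequency` profile is the classic matches-per-residue statistic
with overlapping occurrences counted by start position.

## Synthetic data

`random_protein` draws i.i.d. residues from a user-given composition with a
seeded NumPy generator (no global state), and `implant_motif` overwrites a
window with a motif, preserving length.  Together they build substrates with
known ground truth — e.g. a motif flanked by guaranteed cut sites in an
otherwise cut-free backbone — used to show the pipeline recovers implanted
candidates.  The generator emulates only residue composition; real storage
proteins have repeat structure, domain composition bias and signal peptides
that i.i.d. sequences lack, so passing recovery tests demonstrate engine
correctness, not realistic discovery rates on natural proteomes.

## Determinism and problem sizes

Every ranking and pooling step has a total, documented sort order, so a
fixed configuration and rule set reproduce byte-identical outputs.  The
test suite and the acceptance script run the full eight-protein proteome
against all seven enzymes, engine-vs-oracle agreement on a few hundred
seeded random substrates (length 60–80), and a 50-trial motif-recovery
experiment; the complete suite finishes in a few seconds on one CPU.
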
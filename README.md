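# oatpep

In silico release and screening of bioactive peptides from the storage
proteins of common oat (*Avena sativa*).

Food proteins are a reservoir of short peptides (typically 2–30 residues)
that, once released by proteolysis, can inhibit the enzymes of the
renin–angiotensin–aldosterone system — renin (EC 3.4.23.15) and the
angiotensin-I-converting enzyme (ACE-I, EC 3.4.15.1), both targets for
lowering blood pressure — or dipeptidyl peptidase-IV (DPP-IV, EC 3.4.14.5),
a target in type-2 diabetes.  `oatpep` implements the standard desk workflow
for mining such peptides from a proteome:

1. **Exhaustive in silico digestion** of each protein with food-grade
   proteases (papain, ficin by default).  A protease is a data file of
   positional specificity rules in Schechter–Berger notation (P4…P2′ around
   the scissile bond); every bond matched by a rule and no exception is cut.
2. **Physicochemical characterisation** of the released peptides: average
   and monoisotopic mass (ExPASy residue-mass convention), charged and
   hydrophobic residue fractions, and a water-solubility call — *good* iff
   the peptide carries at least one charged residue (D/E/K/R) per five
   residues.
3. **Known-peptide matching** against a packaged table of peptides already
   reported as ACE-I or DPP-IV inhibitors (with BIOPEP identifiers and
   IC50s); unmatched peptides are *novel*.
4. **Positional bioactivity criteria** per target: renin — hydrophobic
   N-terminus (A,G,V,L,I,P,F,M,W) *and* bulky C-terminus (W,V,I,L,Y,M,F);
   ACE-I — hydrophobic/charged N-terminal residues and aromatic, Leu, Pro or
   K/R C-terminus; DPP-IV — hydrophobic/aromatic N-terminus *or* the Xaa-Pro
   motif (Pro at the second residue from the N-terminus).
5. **Gastrointestinal resistance**: a peptide is predicted to survive
   digestion iff none of chymotrypsin (high and low specificity), pepsin
   (pH 1.3 and pH > 2) or trypsin cuts any of its internal bonds.
6. **Deterministic ranking** of candidates (external ranker score if
   supplied, then number of targets passed, then sequence).

The eight main oat storage proteins (11S and 12S globulins, five avenins,
tryptophanin/2S albumin; UniProt Q38780, P12615, P80356, Q09114, Q09097,
Q09095, P27919, A7U440) ship with the package, so the whole pipeline runs
offline.

## Worked example

```python
>>> from oatpep import (load_oat_proteins, load_enzyme, digest,
...                     average_mass, predict_solubility,
...                     evaluate_criteria, is_resistant, gi_panel)
>>> proteins = load_oat_proteins()
>>> papain = load_enzyme("papain")
>>> result = digest(proteins[0], papain)          # 11S globulin, 527 residues
>>> len(result.cut_sites), len(result.peptides)
(187, 188)
>>> {"CPA", "WCY"} <= {p.sequence for p in result.peptides}
True
```

Papain cuts the 11S globulin at 187 bonds, releasing 188 fragments that
include the tripeptides CPA and WCY.  Screening them:

```python
>>> evaluate_criteria("WCY", "renin").overall_pass   # W hydrophobic, Y bulky
True
>>> evaluate_criteria("CPA", "dppiv").motif_pass     # Xaa-Pro motif
True
>>> round(average_mass("FG"), 3)                     # known ACE-I inhibitor
222.244
>>> predict_solubility("WCY")
('poor', '0 charged residue(s) in 3 (fraction 0.00 < 0.2)')
>>> is_resistant("CPA", gi_panel()).resistant
True
```

WCY satisfies the renin criteria and CPA the DPP-IV Xaa-Pro motif; CPA is
the only candidate predicted to survive the five-enzyme gastrointestinal
panel.  The same workflow runs end to end from the shell:

```sh
oatpep run --out-dir out/            # candidates.tsv, peptides.fasta, report.json
oatpep validate-rules                # release-table calibration coverage
```

`oatpep validate-rules` reports, for every validation peptide (the known
table plus the nine synthesised candidates FFG, IFFFL, PFL, WWK, WCY, FPIL,
CPA, FLLA, FEPL), whether the current papain/ficin tables release it from
the packaged proteome, and prints per-bond diagnostics for any miss; the
shipped tables reach 25/25 (100%).  The papain and ficin tables are
calibrated starting points, not literature tables — see `docs/methods.md`.

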
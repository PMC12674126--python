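# Methods

## The model

The actin fold divides into four subdomains (SD1–SD4). The G-to-F
transition — the conformational change a monomer undergoes when it joins a
filament — is, to first order, a rigid rotation of the SD1/SD2 half of the
molecule relative to the SD3/SD4 half about the axis through the SD1 and
SD3 centers of mass. The package quantifies it as the torsion angle φ
through the four subdomain centers of mass, ordered SD2–SD1–SD3–SD4, so
that the rotation axis of the torsion is exactly that SD1–SD3 hinge.
Reported reference points: twisted G-actin ≈ −24°, flattened F-actin ≈ −6°.

Subdomains are realized as the intersection of the canonical residue
ranges (author numbering; see README) with the chain's modeled residues.
Residues were chosen (by the field) to be present across commonly compared
structures; gaps are tolerated, with a warning below 80% coverage of a
subdomain and a hard error only when a subdomain is entirely unmodeled —
silent use of a half-disordered subdomain would bias its center of mass.

### Torsion sign convention

Right-handed IUPAC convention, identical to Bio.PDB's `calc_dihedral`
(verified to 1e-12° on random quadruples). Under this convention the
twisted state is strongly negative and flattening moves φ toward zero.
Note the IUPAC torsion is *invariant* under reversing the four points
(it reads the same from either end of the chain); it is negated by a
mirror reflection. The property tests assert exactly these identities.

### Center-of-mass weighting

Default: mass-weighted over all non-hydrogen protein atoms of the
subdomain residues (matching the default behavior of common molecular
viewers). `geometric` (unit weights) and `ca` (Cα only) are available;
on the synthetic fixtures, whose pseudo-atoms are carbons, all three
coincide.

### Classification thresholds

`F_like` for φ ≥ −12°, `G_like` for φ ≤ −13.5°, else `intermediate`.
Published F-like dihedrals span −6.2…−10.9° and G-like −14.8…−23.6°;
these defaults separate both groups with ≥ 1° margin (1.1° on the F side,
1.3° on the G side). A G threshold of −14° would leave only 0.8° of margin
to the most flattened G-like structure (−14.8°), so the boundary is placed
slightly higher; both thresholds live in `AnalysisConfig`, not in code.

### ΔSD1 / ΔSD2 offsets

The query chain is superposed onto a reference over the SD3∪SD4 Cα pairs
(the conformationally rigid core), then the offsets of the SD1 and SD2
centers of mass are measured. ΔSD1 is reported both as a displacement (Å)
and as the angle subtended at the *reference* SD3 center of mass between
the two SD1 centers — the angular form is scale-free and closer to how
subdomain swings are usually quoted. The superposition uses `trim="none"`
by default; published matched-Cα counts from other programs can differ by
a few residues because their outlier rejection is not documented, so
matched counts should be treated as approximate (±5) when comparing.

### W-loop gate

d(Tyr143 OH, Gly168 O) is the gate hydrogen bond: ≤ 5 Å is called closed
(published closed values reach ~4.1 Å, so 5 Å leaves margin), ≥ 8 Å open
(published open-state values span 8–12 Å), between is `intermediate`.
d(Tyr143 Cα, Tyr169 Cα) tracks the W-loop/pocket width, which moves much
less than the gate itself. Missing atoms raise errors naming the atom —
a gate distance computed from a partially modeled tyrosine is worse than
no number.

### Tilt / displacement

Two structures (e.g. a trimeric nucleus and a filament model) are anchored
by Kabsch-fitting one subunit pair over all common Cα; the probe subunit's
deviation is then reported as (i) the displacement of a probe atom
(default Asp244 Cα, an SD4 landmark) and (ii) the rotation angle of the
residual Kabsch fit between the probe chains. The rotation angle uses the
atan2 form (norm of the skew part vs trace), which is numerically stable
near 0° where the arccos form loses half the significant digits.

### SASA and buried area

Shrake–Rupley sphere sampling with a deterministic golden-spiral
(Fibonacci) lattice — no RNG, so areas are exactly reproducible and the
complexed-state per-atom area can never exceed the free-state area (the
exposed point set only shrinks when neighbors are added). vdW radii:
C 1.70, N 1.55, O 1.52, S 1.80, others 1.80 Å; probe 1.4 Å; 960 points
per atom (doubling to 1920 changes fixture areas by < 1%). Interface
area follows the half-of-SASA-loss convention, so values are comparable
to standard interface servers within algorithm/radius tolerance — not
bit-exactly, since those parameterizations are unpublished.

### Trajectories

Multi-model PDB is the trajectory format; frames with missing atoms fail
loudly naming the frame (silent skipping would bias open fractions). The
open fraction is the plain counting statistic #{d_gate ≥ threshold}/n at
a default threshold of 8 Å. Published MD open fractions (~40% for
monomeric actin, ~10% for a flattened nucleus subunit) require tens of
nanoseconds of MD and are *not* reproduced here; the package's contract
is exact recovery of generator parameters on synthetic trajectories.

## The synthetic generator

`make_conformer` places four Gaussian pseudo-atom clusters at center
sites whose SD2–SD1–SD3–SD4 torsion equals `phi_target` exactly
(clusters are re-centered after sampling so the mass-weighted center of
mass hits the site to machine precision). Geometry scales: SD1–SD3 hinge
24 Å, SD2 and SD4 arms 13 Å at 105° from the hinge — actin-sized, fixed
once. Residue numbers are real author numbers inside the canonical
ranges, so partitioning, atom lookup and I/O run identically on synthetic
and deposited structures. Tyr143 (Cα, OH) is placed *after* noise,
relative to the final Gly168 O and Tyr169 Cα positions, so gate distances
are exact regardless of noise; Tyr143 lies outside every subdomain range
and therefore never perturbs φ.

`twist_series` rotates the SD1+SD2 block about the realized SD1–SD3
center-of-mass axis. Because that axis is the torsion's own rotation
axis, the measured φ shifts by exactly the applied angle — the series is
exactly linear even on noisy base conformers, which is what makes the
monotonicity and single-class-flip tests sharp rather than statistical.

`make_gate_trajectory` switches Tyr143 OH between two exact distances
(3.5 / 10 Å defaults, matching the shut and open states) either iid or
by a Markov process (stay with probability s, else resample
Bernoulli(p_open) — stationary distribution exactly p_open, per-step
switch probability 2·p_open·(1−p_open)·(1−s)). The true state sequence is
kept in metadata so statistics are tested against ground truth, under
autocorrelation as well as iid.

What a green synthetic test does **not** establish: agreement with
published values measured on deposited coordinates (real side-chain
geometry, altloc ambiguity, lattice contacts), PISA-identical interface
areas, or MD-derived gate kinetics. The synthetic fixtures validate the
measurement machinery, not the biology.

### Noise-recovery bound

With 0.2 Å isotropic per-coordinate noise on 50-atom subdomains, each
center of mass acquires ≈ 0.028 Å of error; through ~13 Å lever arms this
propagates to a per-conformer φ error with σ ≈ 0.2°. The documented 0.5°
recovery bound is therefore a ≈ 2.5σ statistical bound: it holds for the
suite's fixed seeds (worst case 0.495° over the 31-point grid) but is
close to the line by construction, and with generator-default atom counts
(SD2 has only 22 residues) the worst case rises to ≈ 0.7°. The tolerance
was not widened to hide this; treat per-conformer noisy φ values as ±0.5°
at ~2σ confidence.

## Numerical choices

* Kabsch: SVD with the determinant-sign flip on the smallest singular
  vector, so mirror-image inputs yield a proper rotation with honest
  residual RMSD; rank-deficient (collinear) point sets raise rather than
  return an arbitrary rotation. Verified against scipy's
  `align_vectors` and a dense-rotation-grid brute force (1e-3 Å).
* Torsion: standard atan2 formulation; collinear triples raise an
  undefined-torsion error rather than returning 0.
* Altloc resolution: highest occupancy, ties broken by altloc letter;
  fully deterministic.
* PDB output refuses residue numbers > 9999 (fixed-width overflow)
  rather than wrapping; round trips reproduce coordinates to the format's
  0.001 Å precision.
* Unknown elements get carbon's mass with a warning — a mistyped element
  should nudge a center of mass, not abort an analysis.

## Known limitations

* Residue matching is by author numbering only (shared across actin
  depositions); no sequence alignment, so renumbered depositions need
  pre-mapping.
* Single-character chain ids only in PDB output (format limitation);
  multi-character mmCIF chain ids parse but cannot round-trip to PDB.
* Binary trajectory formats (XTC/DCD) are not read; convert to
  multi-model PDB first.
* Interface areas on very small contacts (< ~200 Å²) carry the largest
  relative lattice error; compare trends, not single digits.
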
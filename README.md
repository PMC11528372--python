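# rhodotools

Quantitative characterization of microbial rhodopsins — light-driven,
retinal-binding seven-helix membrane proteins whose best-known members pump
ions across the cell membrane. Establishing that a newly found opsin gene is,
say, a yellow-light-driven outward proton pump takes a chain of small,
well-defined analyses, and `rhodotools` implements that chain as a tested
Python library with a CLI:

* **Sequence** (`opsinseq`) — map a query opsin onto bacteriorhodopsin (BR)
  numbering by global affine-gap alignment, read off the functional residues
  (85/89/96/194/204/212/216), classify the three-letter transport motif
  (DTD/DTS → H⁺ pump, NDQ → Na⁺ pump, NTQ → Cl⁻ pump, …), and check that a
  stable retinal Schiff base can form (Lys at 216 plus carboxylates at 85
  and 212).
* **UV–Vis** (`uvvis`) — λmax at sub-grid resolution, dark/light adaptation
  comparison, and pH-titration analysis with the Henderson–Hasselbalch model
  `A(pH) = A₀ + Σᵢ ΔAᵢ / (1 + 10^(pKaᵢ − pH))` for one or two pKa values,
  with AICc model selection and boundary-aware reporting (an estimate
  outside the sampled pH range is reported as an inequality such as `<1.2`).
* **Photocycle** (`photocycle`) — the irreversible sequential scheme
  ground → K → M → ground with closed-form concentrations
  `c_K = f·e^(−k_KM t)`, `c_M = f·k_KM/(k_KM−k_MP)·(e^(−k_MP t) − e^(−k_KM t))`;
  K/M/bleach assignment in flash-photolysis ΔA(λ,t) matrices, M-decay
  exponential fitting, photocycle turnover time, pyranine proton-release
  analysis, and a global two-rate fit.
* **HPLC** (`chromaret`) — retinal isomer composition by extinction-corrected
  peak areas: `fractionᵢ = (areaᵢ/εᵢ) / Σⱼ(areaⱼ/εⱼ)`.
* **Pump assay** (`pumpassay`) — light-gated pH traces of cell suspensions:
  drift-corrected initial slopes and classification against the CCCP
  protonophore control (acidification abolished by CCCP ⇒ outward H⁺ pump).
* **Structure** (`structcmp`) — alignment-guided Cα pairing and Kabsch (SVD)
  superposition RMSD between PDB structures.
* **Synthetic data** (`synthgen`) — seeded generators for every modality
  with recorded ground truth, so every analysis is scored by parameter
  recovery.

## Worked example

Simulate a complete characterization of one DTS-motif proton pump and
analyze it end to end:

```bash
rhodotools pipeline --seed 7 --out-dir demo/
```

prints (abridged):

```json
{
 "motif": "DTS",
 "predicted_function": "outward H+ pump",
 "schiff_base_ok": true,
 "lambda_max_nm": 569.2666538896372,
 "m_decay_ms^-1": 0.0008996657683034449,
 "m_decay_truth_ms^-1": 0.0009,
 "all_trans_fraction": 0.7580000000000001,
 "pump_classification": "outward H+ pump"
}
```

Reading: the simulated gene carries Asp-Thr-Ser at BR 85/89/96 (a proton-pump
motif with Ser at the donor site) and can form the retinal Schiff base; its
absorption maximum is recovered at ~570 nm from a noisy spectrum; the M
intermediate decays at ~0.0009 ms⁻¹ (an unusually long-lived M, recovered
within 0.04% of the generator's truth); the dark-adapted retinal is 75.8%
all-trans; and illumination-induced acidification abolished by CCCP
classifies it as an outward H⁺ pump.

The same analyses are available on files: `rhodotools lambda-max`,
`titrate`, `photocycle`, `hplc`, `pump`, `motif`, `rmsd`, and
`simulate …` to generate datasets with ground-truth sidecars. Library use
mirrors the CLI one-to-one (see docstrings in each module).

## Documentation

`docs/methods.md` describes the models, their assumptions, the defaults and
their units, what the synthetic generators do and do not emulate, and the
numerical choices (tolerances, tie-breaks, degenerate cases).
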
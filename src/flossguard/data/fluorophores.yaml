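# Packaged fluorophore emission models, version 1.
#
# Each material carries, per excitation wavelength (nm), a list of Gaussian
# emission components (center_nm, fwhm_nm, amplitude).  Amplitudes are in
# spectrum-analyzer counts, on the same scale as the 10,000-count abnormality
# threshold.  Calcium content is in mg per 100 g of material.
#
# The component values are a single frozen calibration chosen so that the
# packaged library reproduces the known qualitative behaviour of these
# materials under 310 nm (UVB) and 365 nm (UVA) excitation:
#   - bones and calcium-rich / plastic materials peak in the 400-500 nm band
#     under UVB and cross the 10,000-count line there;
#   - meats, fish floss, and everything under UVA peak in the 500-600 nm band;
#   - raw salmon and raw cod (calcium >= 6 mg/100 g) peak short under UVB,
#     but only raw cod carries enough signal inside the 405/10 nm camera
#     window to register on the imaging side;
#   - the largest bone-vs-floss spectral contrast for swordfish sits in the
#     400-410 nm window.
version: 1
materials:
  # ---- swordfish --------------------------------------------------------
  - name: swordfish_bone
    kind: bone
    cooking_state: "n/a"
    calcium_mg_per_100g: 20000
    emission:
      310:
        - {center_nm: 410, fwhm_nm: 110, amplitude: 30000}
        - {center_nm: 560, fwhm_nm: 150, amplitude: 2000}
      365:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 18000}
  - name: swordfish_raw
    kind: meat
    cooking_state: raw
    calcium_mg_per_100g: 4
    emission:
      310:
        - {center_nm: 560, fwhm_nm: 110, amplitude: 9000}
      365:
        - {center_nm: 560, fwhm_nm: 120, amplitude: 15000}
  - name: swordfish_steamed
    kind: meat
    cooking_state: steamed
    calcium_mg_per_100g: 2
    emission:
      310:
        - {center_nm: 560, fwhm_nm: 115, amplitude: 8000}
      365:
        - {center_nm: 560, fwhm_nm: 120, amplitude: 13000}
  - name: swordfish_floss
    kind: meat
    cooking_state: floss
    calcium_mg_per_100g: 2
    emission:
      310:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 8000}
        - {center_nm: 430, fwhm_nm: 60, amplitude: 3200}
      365:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 20000}
  # ---- salmon -----------------------------------------------------------
  - name: salmon_bone
    kind: bone
    cooking_state: "n/a"
    calcium_mg_per_100g: 22000
    emission:
      310:
        - {center_nm: 410, fwhm_nm: 105, amplitude: 29000}
        - {center_nm: 560, fwhm_nm: 150, amplitude: 2200}
      365:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 17000}
  - name: salmon_raw
    kind: meat
    cooking_state: raw
    calcium_mg_per_100g: 7
    emission:
      310:
        - {center_nm: 485, fwhm_nm: 55, amplitude: 12000}
        - {center_nm: 560, fwhm_nm: 100, amplitude: 7000}
      365:
        - {center_nm: 560, fwhm_nm: 120, amplitude: 16000}
  - name: salmon_steamed
    kind: meat
    cooking_state: steamed
    calcium_mg_per_100g: 3.5
    emission:
      310:
        - {center_nm: 560, fwhm_nm: 115, amplitude: 8500}
      365:
        - {center_nm: 560, fwhm_nm: 120, amplitude: 14000}
  - name: salmon_floss
    kind: meat
    cooking_state: floss
    calcium_mg_per_100g: 3.5
    emission:
      310:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 7500}
        - {center_nm: 430, fwhm_nm: 60, amplitude: 2800}
      365:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 19000}
  # ---- tuna -------------------------------------------------------------
  - name: tuna_bone
    kind: bone
    cooking_state: "n/a"
    calcium_mg_per_100g: 18000
    emission:
      310:
        - {center_nm: 410, fwhm_nm: 115, amplitude: 31000}
        - {center_nm: 560, fwhm_nm: 150, amplitude: 1800}
      365:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 18500}
  - name: tuna_raw
    kind: meat
    cooking_state: raw
    calcium_mg_per_100g: 5
    emission:
      310:
        - {center_nm: 560, fwhm_nm: 110, amplitude: 9500}
      365:
        - {center_nm: 560, fwhm_nm: 120, amplitude: 15500}
  - name: tuna_steamed
    kind: meat
    cooking_state: steamed
    calcium_mg_per_100g: 2.5
    emission:
      310:
        - {center_nm: 560, fwhm_nm: 115, amplitude: 8200}
      365:
        - {center_nm: 560, fwhm_nm: 120, amplitude: 13500}
  - name: tuna_floss
    kind: meat
    cooking_state: floss
    calcium_mg_per_100g: 2.5
    emission:
      310:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 8200}
        - {center_nm: 430, fwhm_nm: 60, amplitude: 3000}
      365:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 19500}
  # ---- cod --------------------------------------------------------------
  - name: cod_bone
    kind: bone
    cooking_state: "n/a"
    calcium_mg_per_100g: 26000
    emission:
      310:
        - {center_nm: 410, fwhm_nm: 110, amplitude: 32000}
        - {center_nm: 560, fwhm_nm: 150, amplitude: 2000}
      365:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 19000}
  - name: cod_raw
    kind: meat
    cooking_state: raw
    calcium_mg_per_100g: 16
    emission:
      310:
        - {center_nm: 430, fwhm_nm: 80, amplitude: 16000}
        - {center_nm: 560, fwhm_nm: 110, amplitude: 5000}
      365:
        - {center_nm: 560, fwhm_nm: 120, amplitude: 15000}
  - name: cod_steamed
    kind: meat
    cooking_state: steamed
    calcium_mg_per_100g: 5
    emission:
      310:
        - {center_nm: 560, fwhm_nm: 115, amplitude: 8800}
      365:
        - {center_nm: 560, fwhm_nm: 120, amplitude: 14500}
  - name: cod_floss
    kind: meat
    cooking_state: floss
    calcium_mg_per_100g: 5
    emission:
      310:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 8500}
        - {center_nm: 430, fwhm_nm: 60, amplitude: 3100}
      365:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 20500}
  # ---- exclusion / proxy materials --------------------------------------
  - name: calcium_carbonate
    kind: calcium_powder
    cooking_state: "n/a"
    calcium_mg_per_100g: 39200
    emission:
      310:
        - {center_nm: 412, fwhm_nm: 55, amplitude: 40000}
        - {center_nm: 560, fwhm_nm: 120, amplitude: 3000}
      365:
        - {center_nm: 560, fwhm_nm: 120, amplitude: 10000}
  - name: fingernail
    kind: fingernail
    cooking_state: "n/a"
    calcium_mg_per_100g: 100
    emission:
      310:
        - {center_nm: 412, fwhm_nm: 65, amplitude: 12500}
        - {center_nm: 560, fwhm_nm: 120, amplitude: 2500}
      365:
        - {center_nm: 560, fwhm_nm: 120, amplitude: 9000}
  - name: pvc
    kind: plastic
    cooking_state: "n/a"
    calcium_mg_per_100g: 0
    emission:
      310:
        - {center_nm: 435, fwhm_nm: 85, amplitude: 16000}
      365:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 8000}
  - name: emu
    kind: plastic
    cooking_state: "n/a"
    calcium_mg_per_100g: 0
    emission:
      310:
        - {center_nm: 440, fwhm_nm: 85, amplitude: 14500}
      365:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 7500}
  - name: rubber
    kind: plastic
    cooking_state: "n/a"
    calcium_mg_per_100g: 0
    emission:
      310:
        - {center_nm: 445, fwhm_nm: 85, amplitude: 13000}
      365:
        - {center_nm: 560, fwhm_nm: 130, amplitude: 7000}
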
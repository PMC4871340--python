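# Prediction regions, monitors, and Ballesteros-Weinstein annotations for
# the beta-2 adrenergic receptor (author PDB residue numbering).
regions:
  gprotein:
    rmsf_region: {residue_range: [265, 286]}   # lower half of helix 6
    pcc_region_a: {residue_range: [265, 286]}  # helix 6 (6.27-6.48)
    pcc_region_b: {residue_range: [117, 131]}  # helix 3 (3.36-3.50)
  barrestin:
    rmsf_region: {residues: [50, 52, 53, 56, 323, 324, 325]}  # helix 1 set + 7.50-7.52
    pcc_region_a: {residues: [50, 52, 53, 56]}                # helix 1 (1.49-1.55 subset)
    pcc_region_b: {residue_range: [319, 325]}                 # helix 7 (7.46-7.52)

monitors:
  helix3_helix6_distance: [131, 272]        # R131(3.50) - L272(6.34) C-alpha
  npxxy_rmsd: {residue_range: [322, 327], backbone: true}
  connector_rmsd: {residues: [121, 282], heavy: true}

bw_labels:
  "50": "1.49"
  "52": "1.51"
  "53": "1.52"
  "56": "1.55"
  "79": "2.50"
  "113": "3.32"
  "114": "3.33"
  "117": "3.36"
  "121": "3.40"
  "122": "3.41"
  "131": "3.50"
  "219": "5.58"
  "265": "6.27"
  "268": "6.30"
  "271": "6.33"
  "272": "6.34"
  "275": "6.37"
  "278": "6.40"
  "282": "6.44"
  "285": "6.47"
  "286": "6.48"
  "289": "6.51"
  "308": "7.35"
  "309": "7.36"
  "312": "7.39"
  "319": "7.46"
  "322": "7.49"
  "323": "7.50"
  "324": "7.51"
  "325": "7.52"
  "326": "7.53"
  "327": "7.54"
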
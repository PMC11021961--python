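# Default derived glycan trait catalog: 47 traits, IGP28-IGP74, evaluated
# over the total-area-normalized fractions of the quantified compositions.
# This catalog is the package's own documented trait set; replace it to
# reproduce a study-specific formula sheet.
- igp_id: IGP28
  name: Neutral glycan fraction
  numerator: "neuac == 0"
- igp_id: IGP29
  name: Sialylated glycan fraction
  numerator: "neuac >= 1"
- igp_id: IGP30
  name: Monosialylated fraction
  numerator: "neuac == 1"
- igp_id: IGP31
  name: Disialylated fraction
  numerator: "neuac == 2"
- igp_id: IGP32
  name: Tri-plus-sialylated fraction
  numerator: "neuac >= 3"
- igp_id: IGP33
  name: Total fucosylation
  numerator: "dhex >= 1"
- igp_id: IGP34
  name: Afucosylated fraction
  numerator: "dhex == 0"
- igp_id: IGP35
  name: High-mannose fraction
  numerator: "structural == 'high_mannose'"
- igp_id: IGP36
  name: Hybrid fraction
  numerator: "structural == 'hybrid'"
- igp_id: IGP37
  name: Complex fraction
  numerator: "structural == 'complex'"
- igp_id: IGP38
  name: Fucosylation of complex glycans
  numerator: "structural == 'complex' and dhex >= 1"
  denominator: "structural == 'complex'"
- igp_id: IGP39
  name: Fucosylation of hybrid glycans
  numerator: "structural == 'hybrid' and dhex >= 1"
  denominator: "structural == 'hybrid'"
- igp_id: IGP40
  name: Fucosylation of neutral glycans
  numerator: "neuac == 0 and dhex >= 1"
  denominator: "neuac == 0"
- igp_id: IGP41
  name: Fucosylation of sialylated glycans
  numerator: "neuac >= 1 and dhex >= 1"
  denominator: "neuac >= 1"
- igp_id: IGP42
  name: Fucosylation of monosialylated glycans
  numerator: "neuac == 1 and dhex >= 1"
  denominator: "neuac == 1"
- igp_id: IGP43
  name: Fucosylation of disialylated glycans
  numerator: "neuac == 2 and dhex >= 1"
  denominator: "neuac == 2"
- igp_id: IGP44
  name: Sialylation of complex glycans
  numerator: "structural == 'complex' and neuac >= 1"
  denominator: "structural == 'complex'"
- igp_id: IGP45
  name: Sialylation of fucosylated glycans
  numerator: "dhex >= 1 and neuac >= 1"
  denominator: "dhex >= 1"
- igp_id: IGP46
  name: Sialylation of afucosylated glycans
  numerator: "dhex == 0 and neuac >= 1"
  denominator: "dhex == 0"
- igp_id: IGP47
  name: Monosialylated share of sialylated glycans
  numerator: "neuac == 1"
  denominator: "neuac >= 1"
- igp_id: IGP48
  name: Disialylated share of sialylated glycans
  numerator: "neuac == 2"
  denominator: "neuac >= 1"
- igp_id: IGP49
  name: Tri-plus-sialylated share of sialylated glycans
  numerator: "neuac >= 3"
  denominator: "neuac >= 1"
- igp_id: IGP50
  name: Biantennary complex fraction
  numerator: "structural == 'complex' and hexnac == 4"
- igp_id: IGP51
  name: Triantennary fraction
  numerator: "hexnac == 5"
- igp_id: IGP52
  name: Tetra-plus-antennary fraction
  numerator: "hexnac >= 6"
- igp_id: IGP53
  name: Branched share of complex glycans
  numerator: "structural == 'complex' and hexnac >= 5"
  denominator: "structural == 'complex'"
- igp_id: IGP54
  name: Biantennary share of complex glycans
  numerator: "structural == 'complex' and hexnac == 4"
  denominator: "structural == 'complex'"
- igp_id: IGP55
  name: Neutral complex fraction
  numerator: "structural == 'complex' and neuac == 0"
- igp_id: IGP56
  name: Sialylated complex fraction
  numerator: "structural == 'complex' and neuac >= 1"
- igp_id: IGP57
  name: Neutral fucosylated fraction
  numerator: "dhex >= 1 and neuac == 0"
- igp_id: IGP58
  name: Sialofucosylated fraction
  numerator: "dhex >= 1 and neuac >= 1"
- igp_id: IGP59
  name: Agalactosylated share of multi-antennary glycans
  numerator: "hexnac >= 4 and hex == 3"
  denominator: "hexnac >= 4"
- igp_id: IGP60
  name: Monogalactosylated share of biantennary glycans
  numerator: "hexnac == 4 and hex == 4"
  denominator: "hexnac == 4"
- igp_id: IGP61
  name: Digalactosylated share of biantennary glycans
  numerator: "hexnac == 4 and hex >= 5"
  denominator: "hexnac == 4"
- igp_id: IGP62
  name: Galactosylated share of complex glycans
  numerator: "structural == 'complex' and hex >= 4"
  denominator: "structural == 'complex'"
- igp_id: IGP63
  name: Undergalactosylated share of complex glycans
  numerator: "structural == 'complex' and hex <= 3"
  denominator: "structural == 'complex'"
- igp_id: IGP64
  name: Small high-mannose share (Man5-Man6)
  numerator: "structural == 'high_mannose' and hex <= 6"
  denominator: "structural == 'high_mannose'"
- igp_id: IGP65
  name: Large high-mannose share (Man7-Man9)
  numerator: "structural == 'high_mannose' and hex >= 7"
  denominator: "structural == 'high_mannose'"
- igp_id: IGP66
  name: Neutral share of complex glycans
  numerator: "structural == 'complex' and neuac == 0"
  denominator: "structural == 'complex'"
- igp_id: IGP67
  name: Fucosylated share of biantennary glycans
  numerator: "hexnac == 4 and dhex >= 1"
  denominator: "hexnac == 4"
- igp_id: IGP68
  name: Fucosylated share of branched glycans
  numerator: "hexnac >= 5 and dhex >= 1"
  denominator: "hexnac >= 5"
- igp_id: IGP69
  name: Sialylated share of biantennary glycans
  numerator: "hexnac == 4 and neuac >= 1"
  denominator: "hexnac == 4"
- igp_id: IGP70
  name: Sialylated share of branched glycans
  numerator: "hexnac >= 5 and neuac >= 1"
  denominator: "hexnac >= 5"
- igp_id: IGP71
  name: Di- to monosialylated ratio
  numerator: "neuac == 2"
  denominator: "neuac == 1"
  transform: ratio
- igp_id: IGP72
  name: Hybrid share of neutral glycans
  numerator: "structural == 'hybrid' and neuac == 0"
  denominator: "neuac == 0"
- igp_id: IGP73
  name: High-mannose to complex ratio
  numerator: "structural == 'high_mannose'"
  denominator: "structural == 'complex'"
  transform: ratio
- igp_id: IGP74
  name: Neutral to sialylated ratio
  numerator: "neuac == 0"
  denominator: "neuac >= 1"
  transform: ratio
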
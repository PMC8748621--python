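# Default trait schema for the Calamansi (Citrus microcarpa) germplasm survey:
# 8 qualitative traits (coded classes) and 29 quantitative traits (units).
traits:
  - {name: Tree shape,            abbreviation: TS,     kind: qualitative, classes: ["1", "2", "3"]}
  - {name: Tree performance,      abbreviation: TP,     kind: qualitative, classes: ["1", "2", "3"]}
  - {name: Tree growth vigor,     abbreviation: TGV,    kind: qualitative, classes: ["1", "2", "3"]}
  - {name: Leaf base,             abbreviation: LB,     kind: qualitative, classes: ["1", "2", "3"]}
  - {name: Fruit shape,           abbreviation: FS,     kind: qualitative, classes: ["1", "2", "3", "4", "5", "6", "7", "8"]}
  - {name: Fruit base shape,      abbreviation: FBS,    kind: qualitative, classes: ["1", "2", "3", "4", "5", "6", "7"]}
  - {name: Fruit top shape,       abbreviation: FTS,    kind: qualitative, classes: ["1", "2", "3", "4", "5", "6"]}
  - {name: Pulp color,            abbreviation: PC,     kind: qualitative, classes: ["1", "2", "3", "4", "5"]}
  - {name: Tree height,           abbreviation: TH,     kind: quantitative, unit: cm}
  - {name: Crown breadth,         abbreviation: CB,     kind: quantitative, unit: cm}
  - {name: Tree height/crown width, abbreviation: TH/CB, kind: quantitative, unit: ""}
  - {name: Tree foot diameter,    abbreviation: TFD,    kind: quantitative, unit: mm}
  - {name: Branch width,          abbreviation: BW,     kind: quantitative, unit: mm}
  - {name: Branch node length,    abbreviation: BNL,    kind: quantitative, unit: mm}
  - {name: Yield per tree,        abbreviation: YPT,    kind: quantitative, unit: count}
  - {name: Petiole length,        abbreviation: PEL,    kind: quantitative, unit: mm}
  - {name: Leaf lamina length,    abbreviation: LLL,    kind: quantitative, unit: mm}
  - {name: Leaf lamina width,     abbreviation: LLW,    kind: quantitative, unit: mm}
  - {name: Leaf shape index,      abbreviation: LSI,    kind: quantitative, unit: ""}
  - {name: Fruit weight,          abbreviation: FW,     kind: quantitative, unit: g}
  - {name: Fruit diameter,        abbreviation: FD,     kind: quantitative, unit: mm}
  - {name: Fruit length,          abbreviation: FL,     kind: quantitative, unit: mm}
  - {name: Fruit shape index,     abbreviation: FSI,    kind: quantitative, unit: ""}
  - {name: Ascorbic acid,         abbreviation: AA,     kind: quantitative, unit: mg/100 mg}
  - {name: Total soluble solids,  abbreviation: TSS,    kind: quantitative, unit: "%"}
  - {name: Titratable acidity,    abbreviation: TA,     kind: quantitative, unit: "%"}
  - {name: Total soluble solids/titratable acidity, abbreviation: TSS/TA, kind: quantitative, unit: ""}
  - {name: Segment number per fruit, abbreviation: SNF, kind: quantitative, unit: count}
  - {name: Seed number per fruit, abbreviation: SNPF,   kind: quantitative, unit: count}
  - {name: Juice ratio,           abbreviation: JR,     kind: quantitative, unit: "%"}
  - {name: Peel thickness,        abbreviation: PT,     kind: quantitative, unit: mm}
  - {name: Oil cell number,       abbreviation: OCN,    kind: quantitative, unit: count}
  - {name: Petal number,          abbreviation: PN,     kind: quantitative, unit: count}
  - {name: Petal length,          abbreviation: PL,     kind: quantitative, unit: mm}
  - {name: Petal width,           abbreviation: PW,     kind: quantitative, unit: mm}
  - {name: Stamen number,         abbreviation: SN,     kind: quantitative, unit: count}
  - {name: Pistil length,         abbreviation: PIL,    kind: quantitative, unit: mm}
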
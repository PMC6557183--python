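{
 "GLY": [
  [
   43,
   [
    "N"
   ]
  ],
  [
   23,
   [
    "CA"
   ]
  ]
 ],
 "ALA": [
  [
   43,
   [
    "N"
   ]
  ],
  [
   13,
   [
    "CA"
   ]
  ],
  [
   33,
   [
    "CB"
   ]
  ]
 ],
 "VAL": [
  [
   43,
   [
    "N"
   ]
  ],
  [
   13,
   [
    "CA",
    "CB"
   ]
  ],
  [
   33,
   [
    "CG1",
    "CG2"
   ]
  ]
 ],
 "LEU": [
  [
   43,
   [
    "N"
   ]
  ],
  [
   13,
   [
    "CA",
    "CG"
   ]
  ],
  [
   23,
   [
    "CB"
   ]
  ],
  [
   33,
   [
    "CD1",
    "CD2"
   ]
  ]
 ],
 "ILE": [
  [
   43,
   [
    "N"
   ]
  ],
  [
   13,
   [
    "CA",
    "CB"
   ]
  ],
  [
   23,
   [
    "CG1"
   ]
  ],
  [
   33,
   [
    "CG2",
    "CD1"
   ]
  ]
 ],
 "PRO": [
  [
   13,
   [
    "CA"
   ]
  ],
  [
   23,
   [
    "CB",
    "CG",
    "CD"
   ]
  ]
 ],
 "PHE": [
  [
   43,
   [
    "N",
    "CD1",
    "CD2",
    "CE1",
    "CE2",
    "CZ"
   ]
  ],
  [
   13,
   [
    "CA"
   ]
  ],
  [
   23,
   [
    "CB"
   ]
  ]
 ],
 "TYR": [
  [
   43,
   [
    "N",
    "CD1",
    "CD2",
    "CE1",
    "CE2"
   ]
  ],
  [
   13,
   [
    "CA"
   ]
  ],
  [
   23,
   [
    "CB"
   ]
  ],
  [
   147,
   [
    "OH"
   ]
  ]
 ],
 "TRP": [
  [
   43,
   [
    "N",
    "CD1",
    "NE1",
    "CE3",
    "CZ2",
    "CZ3",
    "CH2"
   ]
  ],
  [
   13,
   [
    "CA"
   ]
  ],
  [
   23,
   [
    "CB"
   ]
  ]
 ],
 "SER": [
  [
   43,
   [
    "N"
   ]
  ],
  [
   13,
   [
    "CA"
   ]
  ],
  [
   23,
   [
    "CB"
   ]
  ],
  [
   147,
   [
    "OG"
   ]
  ]
 ],
 "THR": [
  [
   43,
   [
    "N"
   ]
  ],
  [
   13,
   [
    "CA",
    "CB"
   ]
  ],
  [
   33,
   [
    "CG2"
   ]
  ],
  [
   147,
   [
    "OG1"
   ]
  ]
 ],
 "CYS": [
  [
   43,
   [
    "N"
   ]
  ],
  [
   13,
   [
    "CA"
   ]
  ],
  [
   23,
   [
    "CB"
   ]
  ],
  [
   147,
   [
    "SG"
   ]
  ]
 ],
 "MET": [
  [
   43,
   [
    "N"
   ]
  ],
  [
   13,
   [
    "CA"
   ]
  ],
  [
   23,
   [
    "CB",
    "CG"
   ]
  ],
  [
   33,
   [
    "CE"
   ]
  ]
 ],
 "ASN": [
  [
   43,
   [
    "N"
   ]
  ],
  [
   13,
   [
    "CA"
   ]
  ],
  [
   23,
   [
    "CB"
   ]
  ],
  [
   93,
   [
    "ND2"
   ]
  ]
 ],
 "GLN": [
  [
   43,
   [
    "N"
   ]
  ],
  [
   13,
   [
    "CA"
   ]
  ],
  [
   23,
   [
    "CB",
    "CG"
   ]
  ],
  [
   93,
   [
    "NE2"
   ]
  ]
 ],
 "ASP": [
  [
   43,
   [
    "N"
   ]
  ],
  [
   13,
   [
    "CA"
   ]
  ],
  [
   23,
   [
    "CB"
   ]
  ]
 ],
 "GLU": [
  [
   43,
   [
    "N"
   ]
  ],
  [
   13,
   [
    "CA"
   ]
  ],
  [
   23,
   [
    "CB",
    "CG"
   ]
  ]
 ],
 "LYS": [
  [
   43,
   [
    "N"
   ]
  ],
  [
   13,
   [
    "CA"
   ]
  ],
  [
   23,
   [
    "CB",
    "CG",
    "CD",
    "CE"
   ]
  ],
  [
   33,
   [
    "NZ"
   ]
  ]
 ],
 "ARG": [
  [
   43,
   [
    "N",
    "NE"
   ]
  ],
  [
   13,
   [
    "CA"
   ]
  ],
  [
   23,
   [
    "CB",
    "CG",
    "CD"
   ]
  ],
  [
   93,
   [
    "NH1",
    "NH2"
   ]
  ]
 ],
 "HIS": [
  [
   43,
   [
    "N",
    "CD2",
    "CE1",
    "ND1"
   ]
  ],
  [
   13,
   [
    "CA"
   ]
  ],
  [
   23,
   [
    "CB"
   ]
  ]
 ],
 "GOL": [
  [
   13,
   [
    "C2"
   ]
  ],
  [
   23,
   [
    "C1",
    "C3"
   ]
  ],
  [
   147,
   [
    "O1",
    "O2",
    "O3"
   ]
  ]
 ],
 "EDO": [
  [
   23,
   [
    "C1",
    "C2"
   ]
  ],
  [
   147,
   [
    "O1",
    "O2"
   ]
  ]
 ],
 "ACT": [
  [
   33,
   [
    "CH3"
   ]
  ]
 ]
}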
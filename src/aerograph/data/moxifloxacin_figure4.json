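{
  "phase_schema": [
    {
      "name": "in_vitro"
    },
    {
      "name": "in_vivo"
    },
    {
      "name": "phase1"
    },
    {
      "name": "phase2"
    },
    {
      "name": "phase3"
    }
  ],
  "studies": [
    {
      "id": "u1",
      "label": "Ji et al. 1998",
      "phase": "in_vitro",
      "year": 1998,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "v1",
      "label": "Ji et al. 1998",
      "phase": "in_vivo",
      "year": 1998,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "u2",
      "label": "Gillespie et al. 1999",
      "phase": "in_vitro",
      "year": 1999,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "v2",
      "label": "Miyazaki et al. 1999",
      "phase": "in_vivo",
      "year": 1999,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "v3",
      "label": "Lounis et al. 2001",
      "phase": "in_vivo",
      "year": 2001,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "v4",
      "label": "Yoshimatsu et al. 2002",
      "phase": "in_vivo",
      "year": 2002,
      "seq": 0,
      "outcome": "inconclusive",
      "status": "completed"
    },
    {
      "id": "w1",
      "label": "Gosling et al. 2003",
      "phase": "phase1",
      "year": 2003,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "w2",
      "label": "Pletz et al. 2004",
      "phase": "phase1",
      "year": 2004,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "v5",
      "label": "Nuermberger et al. 2004",
      "phase": "in_vivo",
      "year": 2004,
      "seq": 0,
      "outcome": "inconclusive",
      "status": "completed"
    },
    {
      "id": "w3",
      "label": "Gillespie et al. 2005",
      "phase": "phase1",
      "year": 2005,
      "seq": 0,
      "outcome": "negative",
      "status": "completed"
    },
    {
      "id": "w4",
      "label": "Johnson et al. 2006",
      "phase": "phase1",
      "year": 2006,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "x1",
      "label": "Burman et al. 2006",
      "phase": "phase2",
      "year": 2006,
      "seq": 0,
      "outcome": "negative",
      "status": "completed"
    },
    {
      "id": "u3",
      "label": "Shandil et al. 2007",
      "phase": "in_vitro",
      "year": 2007,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "w5",
      "label": "Nijland et al. 2007",
      "phase": "phase1",
      "year": 2007,
      "seq": 0,
      "outcome": "negative",
      "status": "completed"
    },
    {
      "id": "x2",
      "label": "Rustomjee et al. 2007",
      "phase": "phase2",
      "year": 2007,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "w6",
      "label": "Peloquin et al. 2008",
      "phase": "phase1",
      "year": 2008,
      "seq": 0,
      "outcome": "inconclusive",
      "status": "completed"
    },
    {
      "id": "x3",
      "label": "Conde et al. 2009",
      "phase": "phase2",
      "year": 2009,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "x4",
      "label": "Dorman et al. 2009",
      "phase": "phase2",
      "year": 2009,
      "seq": 0,
      "outcome": "negative",
      "status": "completed"
    },
    {
      "id": "x5",
      "label": "Wang et al. 2009",
      "phase": "phase2",
      "year": 2009,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "A",
      "label": "Option A: in vivo discordance mechanisms",
      "phase": "in_vivo",
      "year": 2010,
      "seq": 0,
      "outcome": null,
      "status": "contemplated"
    },
    {
      "id": "B",
      "label": "Option B: drug-interaction pharmacokinetics",
      "phase": "phase1",
      "year": 2010,
      "seq": 0,
      "outcome": null,
      "status": "contemplated"
    },
    {
      "id": "C",
      "label": "Option C: further phase 2 efficacy",
      "phase": "phase2",
      "year": 2010,
      "seq": 0,
      "outcome": null,
      "status": "contemplated"
    },
    {
      "id": "D",
      "label": "Option D: decisive phase 3 effectiveness",
      "phase": "phase3",
      "year": 2010,
      "seq": 0,
      "outcome": null,
      "status": "contemplated"
    }
  ],
  "edges": [
    {
      "parent": "u1",
      "child": "v1",
      "same_report": true
    },
    {
      "parent": "u2",
      "child": "w1",
      "same_report": false
    },
    {
      "parent": "u2",
      "child": "w2",
      "same_report": false
    },
    {
      "parent": "u3",
      "child": "w5",
      "same_report": false
    },
    {
      "parent": "u3",
      "child": "w6",
      "same_report": false
    },
    {
      "parent": "v1",
      "child": "v2",
      "same_report": false
    },
    {
      "parent": "v2",
      "child": "v3",
      "same_report": false
    },
    {
      "parent": "v2",
      "child": "w1",
      "same_report": false
    },
    {
      "parent": "v3",
      "child": "v4",
      "same_report": false
    },
    {
      "parent": "v4",
      "child": "v5",
      "same_report": false
    },
    {
      "parent": "v5",
      "child": "u3",
      "same_report": false
    },
    {
      "parent": "v5",
      "child": "w3",
      "same_report": false
    },
    {
      "parent": "v5",
      "child": "w4",
      "same_report": false
    },
    {
      "parent": "w1",
      "child": "v5",
      "same_report": false
    },
    {
      "parent": "w2",
      "child": "v5",
      "same_report": false
    },
    {
      "parent": "w3",
      "child": "x1",
      "same_report": false
    },
    {
      "parent": "w4",
      "child": "x1",
      "same_report": false
    },
    {
      "parent": "w4",
      "child": "x2",
      "same_report": false
    },
    {
      "parent": "w5",
      "child": "B",
      "same_report": false
    },
    {
      "parent": "w6",
      "child": "x4",
      "same_report": false
    },
    {
      "parent": "x1",
      "child": "w5",
      "same_report": false
    },
    {
      "parent": "x1",
      "child": "w6",
      "same_report": false
    },
    {
      "parent": "x1",
      "child": "x3",
      "same_report": false
    },
    {
      "parent": "x1",
      "child": "x4",
      "same_report": false
    },
    {
      "parent": "x2",
      "child": "x3",
      "same_report": false
    },
    {
      "parent": "x3",
      "child": "x5",
      "same_report": false
    },
    {
      "parent": "x4",
      "child": "A",
      "same_report": false
    },
    {
      "parent": "x4",
      "child": "B",
      "same_report": false
    },
    {
      "parent": "x4",
      "child": "C",
      "same_report": false
    },
    {
      "parent": "x5",
      "child": "C",
      "same_report": false
    },
    {
      "parent": "x5",
      "child": "D",
      "same_report": false
    }
  ]
}
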
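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
      "id": "α1",
      "label": "α1",
      "phase": "in_vitro",
      "year": 2000,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "α2",
      "label": "α2",
      "phase": "in_vitro",
      "year": 2000,
      "seq": 1,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "β1",
      "label": "β1",
      "phase": "in_vivo",
      "year": 2001,
      "seq": 0,
      "outcome": "negative",
      "status": "completed"
    },
    {
      "id": "β2",
      "label": "β2",
      "phase": "in_vivo",
      "year": 2002,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "β3",
      "label": "β3",
      "phase": "in_vivo",
      "year": 2002,
      "seq": 1,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "γ1",
      "label": "γ1",
      "phase": "phase1",
      "year": 2003,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "γ2",
      "label": "γ2",
      "phase": "phase1",
      "year": 2003,
      "seq": 1,
      "outcome": "inconclusive",
      "status": "completed"
    },
    {
      "id": "δ1",
      "label": "δ1",
      "phase": "phase2",
      "year": 2004,
      "seq": 0,
      "outcome": "negative",
      "status": "completed"
    },
    {
      "id": "γ3",
      "label": "γ3",
      "phase": "phase1",
      "year": 2004,
      "seq": 1,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "δ2",
      "label": "δ2",
      "phase": "phase2",
      "year": 2005,
      "seq": 0,
      "outcome": "positive",
      "status": "completed"
    },
    {
      "id": "δ3",
      "label": "δ3",
      "phase": "phase2",
      "year": 2005,
      "seq": 1,
      "outcome": "inconclusive",
      "status": "completed"
    }
  ],
  "edges": [
    {
      "parent": "α1",
      "child": "α2",
      "same_report": false
    },
    {
      "parent": "α1",
      "child": "β1",
      "same_report": false
    },
    {
      "parent": "α2",
      "child": "β2",
      "same_report": false
    },
    {
      "parent": "α2",
      "child": "β3",
      "same_report": false
    },
    {
      "parent": "β2",
      "child": "γ1",
      "same_report": false
    },
    {
      "parent": "β3",
      "child": "γ2",
      "same_report": false
    },
    {
      "parent": "β3",
      "child": "γ3",
      "same_report": false
    },
    {
      "parent": "β3",
      "child": "δ2",
      "same_report": false
    },
    {
      "parent": "γ1",
      "child": "δ1",
      "same_report": false
    },
    {
      "parent": "γ3",
      "child": "δ2",
      "same_report": false
    },
    {
      "parent": "δ1",
      "child": "γ3",
      "same_report": false
    }
  ]
}
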
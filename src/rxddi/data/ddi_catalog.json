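[
  {
    "name": "citalopram",
    "synonyms": ["citalopram", "cipramil", "celexa"],
    "pk_roles": [],
    "pd": false,
    "severity": "none",
    "route": "systemic"
  },
  {
    "name": "omeprazole",
    "synonyms": ["omeprazole", "prilosec", "losec"],
    "pk_roles": ["inhibitor"],
    "pd": false,
    "severity": "none",
    "route": "systemic"
  },
  {
    "name": "lansoprazole",
    "synonyms": ["lansoprazole", "prevacid", "zoton"],
    "pk_roles": ["inhibitor"],
    "pd": false,
    "severity": "none",
    "route": "systemic"
  },
  {
    "name": "diazepam",
    "synonyms": ["diazepam", "valium"],
    "pk_roles": ["substrate"],
    "pd": false,
    "severity": "none",
    "route": "systemic"
  },
  {
    "name": "amitriptyline",
    "synonyms": ["amitriptyline", "elavil", "triptafen"],
    "pk_roles": ["substrate"],
    "pd": true,
    "severity": "not_recommended",
    "route": "systemic"
  },
  {
    "name": "quinidine",
    "synonyms": ["quinidine", "quinora"],
    "pk_roles": [],
    "pd": true,
    "severity": "contraindicated",
    "route": "systemic"
  },
  {
    "name": "hydroxyzine",
    "synonyms": ["hydroxyzine", "atarax", "ucerax"],
    "pk_roles": [],
    "pd": true,
    "severity": "contraindicated",
    "route": "systemic"
  },
  {
    "name": "ketoconazole",
    "synonyms": ["ketoconazole", "nizoral"],
    "pk_roles": ["inhibitor"],
    "pd": false,
    "severity": "none",
    "route": "topical"
  }
]
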
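{
  "comment": "Kinship surface forms, normalized family-member inventory, and composition classes for compound possessives ('father's father' -> Grandfather).",
  "normalized": {
    "degree1": ["Father", "Mother", "Parent", "Sister", "Brother", "Daughter", "Son", "Child"],
    "degree2": ["Grandmother", "Grandfather", "Grandparent", "Cousin", "Sibling", "Aunt", "Uncle"]
  },
  "surface": {
    "father": "Father", "dad": "Father", "daddy": "Father", "papa": "Father",
    "mother": "Mother", "mom": "Mother", "mum": "Mother", "mommy": "Mother", "mama": "Mother",
    "parent": "Parent", "parents": "Parent",
    "sister": "Sister", "sisters": "Sister", "sis": "Sister",
    "brother": "Brother", "brothers": "Brother",
    "daughter": "Daughter", "daughters": "Daughter",
    "son": "Son", "sons": "Son",
    "child": "Child", "children": "Child", "kid": "Child", "kids": "Child",
    "grandmother": "Grandmother", "grandma": "Grandmother", "granny": "Grandmother",
    "grandfather": "Grandfather", "grandpa": "Grandfather", "granddad": "Grandfather",
    "grandparent": "Grandparent", "grandparents": "Grandparent",
    "cousin": "Cousin", "cousins": "Cousin",
    "sibling": "Sibling", "siblings": "Sibling",
    "aunt": "Aunt", "aunts": "Aunt", "auntie": "Aunt",
    "uncle": "Uncle", "uncles": "Uncle"
  },
  "classes": {
    "Father": ["parent", "M"], "Mother": ["parent", "F"], "Parent": ["parent", "N"],
    "Sister": ["sibling", "F"], "Brother": ["sibling", "M"], "Sibling": ["sibling", "N"],
    "Daughter": ["child", "F"], "Son": ["child", "M"], "Child": ["child", "N"],
    "Grandmother": ["grandparent", "F"], "Grandfather": ["grandparent", "M"],
    "Grandparent": ["grandparent", "N"],
    "Aunt": ["parent_sibling", "F"], "Uncle": ["parent_sibling", "M"],
    "Cousin": ["cousin", "N"]
  },
  "composition": {
    "parent,parent": {"M": "Grandfather", "F": "Grandmother", "N": "Grandparent"},
    "parent,sibling": {"M": "Uncle", "F": "Aunt", "N": null},
    "parent,child": {"M": "Brother", "F": "Sister", "N": "Sibling"},
    "parent_sibling,child": {"M": "Cousin", "F": "Cousin", "N": "Cousin"}
  },
  "exclusion_terms": [
    "partner", "husband", "wife", "spouse", "boyfriend", "girlfriend", "fiance", "fiancee",
    "stepfather", "stepmother", "stepbrother", "stepsister", "stepson", "stepdaughter",
    "in-law", "in-laws", "father-in-law", "mother-in-law", "brother-in-law", "sister-in-law",
    "son-in-law", "daughter-in-law"
  ]
}
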
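{
 "n_selected": 3,
 "texts": {
  "ToyClip": {
   "0": {
    "A": "I think the birds were flying over the church",
    "B": "Two birds flew. A bird sat on the church.",
    "C": "It seems like a bird is flying. The church bells rang."
   },
   "1": {
    "A": "Mr. Bean sat in the kitchen",
    "B": "Mr. Bean was sleeping. Maybe he slept in the kitchen.",
    "C": "The kitchen door closed"
   }
  }
 }
}
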
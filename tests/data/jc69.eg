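;; Jukes-Cantor chain written with nested token loops, wrapped in the
;; trivial single-emitter grammar.
(alphabet (name dna) (token (a c g t)))
(grammar
 (name jc69)
 (rate (u 1.0))
 (chain
  (terminal NUC)
  (&foreach-token tok1
   (&foreach-token tok2
    (&if (&eq tok1 tok2)
     () ;; If tok1 == tok2, expand to an empty list (ignored by parser)
     (mutate (from (tok1)) (to (tok2)) (rate u))))))
 (transform (from (start)) (to (E)) (prob 1))
 (transform (from (E)) (to (NUC E*)) (prob 1))
 (transform (from (E*)) (to (E)) (prob 1))
 (transform (from (E)) (to (E)) (prob 1))
 (transform (from (E)) (to ()) (prob 1)))
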
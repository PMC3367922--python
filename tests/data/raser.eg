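;; Latent slow/fast rate-class chain (RASER-style): JC69 within classes
;; scaled by s or f, class flips at r_sf / r_fs.  Five free parameters.
(alphabet (name dna) (token (a c g t)))
(grammar
 (name raser)
 (rate (s 0.1) (f 2.0) (r_sf 0.01) (r_fs 0.01) (u 1.0))
 (chain
  (hidden-class (row CLASS) (label (s f)))
  (terminal RASER)
  (&foreach class1 (s f)
   (&foreach class2 (s f)
    (&foreach-token tok1
     (&foreach-token tok2
      (&if (&eq class1 class2)
       (&if (&eq tok1 tok2)
        () ;; if class1 == class2 && tok1 == tok2, expand to empty list
        ;; The following line handles the case (class1 == class2 && tok1 != tok2)
        (mutate (from (tok1 class1)) (to (tok2 class2)) (rate u class1)))
       (&if (&eq tok1 tok2)
        ;; The following line handles the case (class1 != class2 && tok1 == tok2)
        (mutate (from (tok1 class1)) (to (tok2 class2)) (rate (&cat r_ class1 class2)))
        ())))))))  ;; if class1 != class2 && tok1 != tok2, expand to empty list
 (transform (from (start)) (to (E)) (prob 1))
 (transform (from (E)) (to (RASER E*)) (prob 1))
 (transform (from (E*)) (to (E)) (prob 1))
 (transform (from (E)) (to (E)) (prob 1))
 (transform (from (E)) (to ()) (prob 1)))
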
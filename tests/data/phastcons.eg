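;; Rate-multiplier phylo-HMM (PhastCons-style): numNonterms nonterminals
;; sharing one substitution model up to per-nonterminal multipliers.
;; The historically printed form of this grammar has one misplaced
;; closing parenthesis in the nonterminal-transition &if (repaired here)
;; and spells the leave probability "changeProb" in the transition rule
;; while the pgroup declares "leaveProb"; readers treat the two names as
;; the same parameter.
(alphabet (name dna) (token (a c g t)))
(grammar
 (name phastcons)

 (&define numNonterms 3)
 (&define SEED 0.001)

 (&foreach-integer nonterminal (1 numNonterms)
  (rate ((&cat r_ nonterminal) SEED)))

 (rate (u 1.0))
 (&foreach-token tok1
  (&foreach-token tok2
   (&if (&eq tok1 tok2)
    () ;; If tok1 == tok2, expand to an empty list (ignored by parser)
    (rate (&cat Q_ tok1 _ tok2) u))))

 (&foreach-integer nonterminal (1 numNonterms)
  (chain
   (terminal (&cat chain_ nonterminal))
   (&foreach-token tok1
    (&foreach-token tok2
     (&if (&eq tok1 tok2)
      ()
      (mutate (from (tok1)) (to (tok2))
       (rate (&cat Q_ tok1 _ tok2) (&cat r_ nonterminal))))))))

 (pgroup (stayProb 0.9) (leaveProb 0.1))

 (&foreach-integer nonterm1 (1 numNonterms)
  ;; Each nonterminal has a transition from start
  (transform (from (start)) (to (nonterm1)) (prob (&/1 numNonterms)))
  ;; Each nonterminal can transition to end - we assign this prob 1
  ;; since the alignment length directs when this transition occurs
  (transform (from (nonterm1)) (to ()) (prob 1))
  (&foreach-integer nonterm2 (1 numNonterms)
   (&if (&eq nonterm1 nonterm2)
    ;; If nonterm1 == nonterm2, this is a self-transition
    (transform (from (nonterm1)) (to (nonterm2)) (prob stayProb))
    ;; Otherwise, this is an inter-nonterminal transition
    ;; with probability changeProb/(numNonterms - 1)
    (transform (from (nonterm1)) (to (nonterm2))
     (prob (&/changeProb (&- numNonterms 1)))))))

 (&foreach-integer nonterminal (1 numNonterms)
  (transform (from (nonterminal)) (to ((&cat chain_ nonterminal) (&cat nonterminal *))))
  (transform (from ((&cat nonterminal *))) (to (nonterminal)))))
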
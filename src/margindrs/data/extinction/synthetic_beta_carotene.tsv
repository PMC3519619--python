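# wavelength_nm	epsilon
450.0	2.25490356e-01
451.0	2.31539890e-01
452.0	2.36014205e-01
453.0	2.38958920e-01
454.0	2.40485504e-01
455.0	2.40766966e-01
456.0	2.40029908e-01
457.0	2.38543328e-01
458.0	2.36604773e-01
459.0	2.34524646e-01
460.0	2.32609587e-01
461.0	2.31145910e-01
462.0	2.30384088e-01
463.0	2.30525169e-01
464.0	2.31709926e-01
465.0	2.34011314e-01
466.0	2.37430640e-01
467.0	2.41897582e-01
468.0	2.47274013e-01
469.0	2.53361320e-01
470.0	2.59910764e-01
471.0	2.66636239e-01
472.0	2.73228698e-01
473.0	2.79371441e-01
474.0	2.84755438e-01
475.0	2.89093900e-01
476.0	2.92135375e-01
477.0	2.93674732e-01
478.0	2.93561580e-01
479.0	2.91705770e-01
480.0	2.88079825e-01
481.0	2.82718318e-01
482.0	2.75714354e-01
483.0	2.67213482e-01
484.0	2.57405467e-01
485.0	2.46514452e-01
486.0	2.34788099e-01
487.0	2.22486305e-01
488.0	2.09870086e-01
489.0	1.97191171e-01
490.0	1.84682770e-01
491.0	1.72551883e-01
492.0	1.60973409e-01
493.0	1.50086187e-01
494.0	1.39991006e-01
495.0	1.30750490e-01
496.0	1.22390693e-01
497.0	1.14904153e-01
498.0	1.08254110e-01
499.0	1.02379570e-01
500.0	9.72008616e-02
501.0	9.26253854e-02
502.0	8.85532525e-02
503.0	8.48825559e-02
504.0	8.15140780e-02
505.0	7.83552780e-02
506.0	7.53234658e-02
507.0	7.23481177e-02
508.0	6.93723365e-02
509.0	6.63535022e-02
510.0	6.32631886e-02
511.0	6.00864495e-02
512.0	5.68205916e-02
513.0	5.34735607e-02
514.0	5.00620688e-02
515.0	4.66095837e-02
516.0	4.31442918e-02
517.0	3.96971318e-02
518.0	3.62999788e-02
519.0	3.29840399e-02
520.0	2.97785043e-02
521.0	2.67094716e-02
522.0	2.37991667e-02
523.0	2.10654335e-02
524.0	1.85214890e-02
525.0	1.61759080e-02
526.0	1.40328052e-02
527.0	1.20921734e-02
528.0	1.03503402e-02
529.0	8.80050252e-03
530.0	7.43330246e-03
531.0	6.23741388e-03
532.0	5.20011114e-03
533.0	4.30779927e-03
534.0	3.54648971e-03
535.0	2.90221121e-03
536.0	2.36135063e-03
537.0	1.91092251e-03
538.0	1.53876998e-03
539.0	1.23370206e-03
540.0	9.85574501e-04
541.0	7.85322201e-04
542.0	6.24952053e-04
543.0	4.97504614e-04
544.0	3.96992833e-04
545.0	3.18325105e-04
546.0	2.57219025e-04
547.0	2.10111120e-04
548.0	1.74066770e-04
549.0	1.46693527e-04
550.0	1.26060080e-04
551.0	1.10622332e-04
552.0	9.91573794e-05
553.0	9.07056503e-05
554.0	8.45210414e-05
555.0	8.00286239e-05
556.0	7.67892838e-05
557.0	7.44705628e-05
558.0	7.28229222e-05
559.0	7.16606584e-05
560.0	7.08467398e-05
561.0	7.02808957e-05
562.0	6.98903630e-05
563.0	6.96227742e-05
564.0	6.94407486e-05
565.0	6.93178190e-05
566.0	6.92353970e-05
567.0	6.91805318e-05
568.0	6.91442723e-05
569.0	6.91204808e-05
570.0	6.91049820e-05
571.0	6.90949576e-05
572.0	6.90885204e-05
573.0	6.90844161e-05
574.0	6.90818180e-05
575.0	6.90801851e-05
576.0	6.90791661e-05
577.0	6.90785347e-05
578.0	6.90781463e-05
579.0	6.90779090e-05
580.0	6.90777651e-05
581.0	6.90776785e-05
582.0	6.90776267e-05
583.0	6.90775959e-05
584.0	6.90775778e-05
585.0	6.90775672e-05
586.0	6.90775610e-05
587.0	6.90775575e-05
588.0	6.90775554e-05
589.0	6.90775543e-05
590.0	6.90775536e-05
591.0	6.90775532e-05
592.0	6.90775530e-05
593.0	6.90775529e-05
594.0	6.90775529e-05
595.0	6.90775528e-05
596.0	6.90775528e-05
597.0	6.90775528e-05
598.0	6.90775528e-05
599.0	6.90775528e-05
600.0	6.90775528e-05
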
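# wavelength_nm	epsilon
450.0	1.06379431e-01
451.0	1.06313371e-01
452.0	1.06115441e-01
453.0	1.05786398e-01
454.0	1.05327498e-01
455.0	1.04740486e-01
456.0	1.04027586e-01
457.0	1.03191492e-01
458.0	1.02235342e-01
459.0	1.01162705e-01
460.0	9.99775581e-02
461.0	9.86842586e-02
462.0	9.72875208e-02
463.0	9.57923859e-02
464.0	9.42041917e-02
465.0	9.25285413e-02
466.0	9.07712702e-02
467.0	8.89384122e-02
468.0	8.70361656e-02
469.0	8.50708581e-02
470.0	8.30489123e-02
471.0	8.09768109e-02
472.0	7.88610629e-02
473.0	7.67081699e-02
474.0	7.45245938e-02
475.0	7.23167252e-02
476.0	7.00908540e-02
477.0	6.78531401e-02
478.0	6.56095877e-02
479.0	6.33660197e-02
480.0	6.11280553e-02
481.0	5.89010891e-02
482.0	5.66902730e-02
483.0	5.45005003e-02
484.0	5.23363916e-02
485.0	5.02022845e-02
486.0	4.81022252e-02
487.0	4.60399636e-02
488.0	4.40189506e-02
489.0	4.20423404e-02
490.0	4.01129953e-02
491.0	3.82334956e-02
492.0	3.64061546e-02
493.0	3.46330396e-02
494.0	3.29160005e-02
495.0	3.12567060e-02
496.0	2.96566916e-02
497.0	2.81174188e-02
498.0	2.66403490e-02
499.0	2.52270348e-02
500.0	2.38792295e-02
501.0	2.25990193e-02
502.0	2.13889778e-02
503.0	2.02523459e-02
504.0	1.91932357e-02
505.0	1.82168582e-02
506.0	1.73297698e-02
507.0	1.65401324e-02
508.0	1.58579779e-02
509.0	1.52954627e-02
510.0	1.48670976e-02
511.0	1.45899304e-02
512.0	1.44836584e-02
513.0	1.45706428e-02
514.0	1.48757969e-02
515.0	1.54263182e-02
516.0	1.62512377e-02
517.0	1.73807637e-02
518.0	1.88454050e-02
519.0	2.06748679e-02
520.0	2.28967362e-02
521.0	2.55349566e-02
522.0	2.86081729e-02
523.0	3.21279660e-02
524.0	3.60970786e-02
525.0	4.05077166e-02
526.0	4.53400307e-02
527.0	5.05608902e-02
528.0	5.61230579e-02
529.0	6.19648694e-02
530.0	6.80105012e-02
531.0	7.41708896e-02
532.0	8.03453289e-02
533.0	8.64237396e-02
534.0	9.22895575e-02
535.0	9.78231510e-02
536.0	1.02905637e-01
537.0	1.07422932e-01
538.0	1.11269846e-01
539.0	1.14354025e-01
540.0	1.16599543e-01
541.0	1.17949948e-01
542.0	1.18370622e-01
543.0	1.17850330e-01
544.0	1.16401901e-01
545.0	1.14062032e-01
546.0	1.10890267e-01
547.0	1.06967264e-01
548.0	1.02392499e-01
549.0	9.72815892e-02
550.0	9.17634390e-02
551.0	8.59774018e-02
552.0	8.00706030e-02
553.0	7.41955339e-02
554.0	6.85079366e-02
555.0	6.31649147e-02
556.0	5.83231088e-02
557.0	5.41366959e-02
558.0	5.07549110e-02
559.0	4.83187749e-02
560.0	4.69567545e-02
561.0	4.67791851e-02
562.0	4.78714573e-02
563.0	5.02862019e-02
564.0	5.40349621e-02
565.0	5.90801083e-02
566.0	6.53279629e-02
567.0	7.26242289e-02
568.0	8.07528118e-02
569.0	8.94389559e-02
570.0	9.83572879e-02
571.0	1.07144884e-01
572.0	1.15418905e-01
573.0	1.22797742e-01
574.0	1.28924094e-01
575.0	1.33487981e-01
576.0	1.36247561e-01
577.0	1.37045682e-01
578.0	1.35820469e-01
579.0	1.32608821e-01
580.0	1.27542459e-01
581.0	1.20836917e-01
582.0	1.12774646e-01
583.0	1.03683967e-01
584.0	9.39159615e-02
585.0	8.38214906e-02
586.0	7.37303397e-02
587.0	6.39341108e-02
588.0	5.46739224e-02
589.0	4.61333793e-02
590.0	3.84366850e-02
591.0	3.16512777e-02
592.0	2.57940239e-02
593.0	2.08398192e-02
594.0	1.67314246e-02
595.0	1.33894724e-02
596.0	1.07217871e-02
597.0	8.63141303e-03
598.0	7.02300975e-03
599.0	5.80750703e-03
600.0	4.90510361e-03
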